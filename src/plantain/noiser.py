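"""Diffusion-inspired generation of training pairs.

The crystal pose is noised along a quadratic severity schedule: at level
``t`` of ``T`` the per-channel standard deviation is ``sigma_max * (t/T)**2``,
with maxima of 4 A for translation, 1.5 rad for the rigid-rotation vector and
2.5 rad for each torsion, over T = 16 levels.  Noise is sampled directly at a
level from the crystal pose (the regression target, the per-atom distance to
the crystal position, needs no Markov chain).

Training pockets arrive pre-aligned to the ligand's crystal frame; when they
come from a different crystal structure of the same protein the alignment is
assumed done upstream (cross-structure pairing is data, not code).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .molio import LigandGraph, PocketDefinition, PocketStructure, extract_pocket, read_ligand
from .posemath import PoseParams, apply_pose

__all__ = [
    "NoiseSchedule",
    "TrainingExample",
    "TrainingComplex",
    "sigma_at",
    "sample_noised_pose",
    "make_training_example",
    "load_training_manifest",
]

CHANNELS = ("translation", "rotation", "torsion")


@dataclass(frozen=True)
class NoiseSchedule:
    """Quadratic noise schedule reaching the per-channel maxima at t = T."""

    timesteps: int = 16
    sigma_max_translation: float = 4.0  # A
    sigma_max_rotation: float = 1.5     # rad, on each rotation-vector component
    sigma_max_torsion: float = 2.5      # rad, per torsional angle

    def __post_init__(self):
        if self.timesteps < 1:
            raise ValueError("timesteps must be >= 1")
        if min(self.sigma_max_translation, self.sigma_max_rotation,
               self.sigma_max_torsion) < 0:
            raise ValueError("sigma_max values must be non-negative")

    def sigma_max(self, channel: str) -> float:
        try:
            return {
                "translation": self.sigma_max_translation,
                "rotation": self.sigma_max_rotation,
                "torsion": self.sigma_max_torsion,
            }[channel]
        except KeyError:
            raise ValueError(f"unknown channel {channel!r}; expected one of {CHANNELS}")


def sigma_at(schedule: NoiseSchedule, t: int, channel: str) -> float:
    """sigma(t) = sigma_max * (t/T)^2 for 1 <= t <= T."""
    if not 1 <= t <= schedule.timesteps:
        raise ValueError(f"timestep {t} outside 1..{schedule.timesteps}")
    return schedule.sigma_max(channel) * (t / schedule.timesteps) ** 2


def wrap_angle(x: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return -((-np.asarray(x) + np.pi) % (2.0 * np.pi) - np.pi)


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_noised_pose(
    crystal: np.ndarray,
    graph: LigandGraph,
    schedule: NoiseSchedule,
    t: int,
    rng_seed,
) -> tuple[np.ndarray, PoseParams]:
    """Noise the crystal pose at severity level ``t``.

    Each translation component ~ N(0, sigma_tr(t)^2), each rotation-vector
    component ~ N(0, sigma_rot(t)^2), each torsion ~ N(0, sigma_tor(t)^2).
    Torsions are kept unwrapped in the returned parameters: an angle and its
    2*pi shift give the identical pose, and the raw draws keep the configured
    noise level empirically verifiable (use :func:`wrap_angle` to normalize
    for display).  Reproducible given the seed.
    """
    rng = _as_rng(rng_seed)
    params = PoseParams(
        translation=rng.normal(0.0, sigma_at(schedule, t, "translation"), size=3),
        rotation=rng.normal(0.0, sigma_at(schedule, t, "rotation"), size=3),
        torsions=rng.normal(0.0, sigma_at(schedule, t, "torsion"), size=graph.n_torsions),
    )
    return apply_pose(crystal, graph, params), params


@dataclass
class TrainingExample:
    """A noised conformation with its per-atom regression targets."""

    noised: np.ndarray        # (L, 3)
    timestep: int             # 1..T
    targets: np.ndarray       # (L,) distance of each atom to its crystal position, A
    pocket: PocketStructure   # pre-aligned to the crystal frame


def make_training_example(
    crystal: np.ndarray,
    graph: LigandGraph,
    pocket: PocketStructure,
    schedule: NoiseSchedule,
    rng_seed,
) -> TrainingExample:
    """Draw t uniformly from 1..T, noise the pose, record D_i = |noised_i - crystal_i|."""
    rng = _as_rng(rng_seed)
    t = int(rng.integers(1, schedule.timesteps + 1))
    noised, _ = sample_noised_pose(crystal, graph, schedule, t, rng)
    targets = np.linalg.norm(noised - np.asarray(crystal, dtype=float), axis=1)
    return TrainingExample(noised=noised, timestep=t, targets=targets, pocket=pocket)


@dataclass
class TrainingComplex:
    """A ligand crystal pose paired with an (aligned) pocket."""

    name: str
    graph: LigandGraph
    crystal: np.ndarray
    pocket: PocketStructure


def load_training_manifest(
    path,
    definition: PocketDefinition | None = None,
) -> list[TrainingComplex]:
    """Load (ligand_sdf, pocket_pdb) pairs from a manifest CSV.

    Columns: ``ligand_sdf``, ``pocket_pdb``, optional ``name``.  Paths are
    resolved relative to the manifest location.  The pocket is extracted
    around the ligand's own crystal pose with the given definition.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("ligand_sdf", "pocket_pdb"):
        if col not in df.columns:
            raise ValueError(f"manifest {path} lacks required column {col!r}")
    complexes = []
    for idx, row in df.iterrows():
        lig_path = path.parent / str(row["ligand_sdf"])
        pdb_path = path.parent / str(row["pocket_pdb"])
        graph, crystal = read_ligand(str(lig_path), format="sdf")
        if crystal is None:
            raise ValueError(f"{lig_path} has no 3D coordinates")
        pocket = extract_pocket(pdb_path, [crystal], definition)
        name = str(row["name"]) if "name" in df.columns else f"complex_{idx}"
        complexes.append(TrainingComplex(name, graph, crystal, pocket))
    return complexes
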