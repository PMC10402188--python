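"""Inference: conformer generation, randomized initialization, L-BFGS.

The docking procedure: run the encoder once to get scoring coefficients,
generate a force-field-relaxed 3D conformer of the ligand, then repeat
``n_restarts`` times: randomize the torsions, place the ligand at the pocket
centroid with a uniformly random rigid rotation and Gaussian translation
noise, and minimize the pose score with L-BFGS over translation, rotation and
torsional angles.  The pose with the lowest final score wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.optimize import minimize as scipy_minimize

from .errors import DockingError
from .molio import LigandGraph, PocketStructure, graph_to_mol
from .posemath import PoseParams, apply_pose, centroid, random_rotation_vector
from .scorer import OracleObjective, PoseObjective, RBFBasis, ScoreCoefficients

__all__ = [
    "DockConfig",
    "RestartInfo",
    "DockResult",
    "generate_conformer",
    "init_pose",
    "minimize_pose",
    "dock",
]


@dataclass(frozen=True)
class DockConfig:
    n_restarts: int = 16
    init_translation_sigma: float = 4.0  # A, Gaussian offset from the pocket centroid
    max_iterations: int = 200
    history_size: int = 10
    tolerance: float = 1e-6              # on both score change and gradient inf-norm
    seed: int = 0

    def __post_init__(self):
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class RestartInfo:
    seed: int
    iterations: int
    initial_score: float
    final_score: float
    score_trace: list[float] = field(default_factory=list)
    failed: bool = False


@dataclass
class DockResult:
    poses: list[np.ndarray]
    scores: list[float]
    best_index: int
    restarts: list[RestartInfo]
    n_failed: int = 0
    n_encoder_calls: int = 0

    @property
    def best_pose(self) -> np.ndarray:
        return self.poses[self.best_index]

    @property
    def best_score(self) -> float:
        return self.scores[self.best_index]


def generate_conformer(graph: LigandGraph, seed: int, max_attempts: int = 5) -> np.ndarray:
    """One low-energy 3D conformer: distance-geometry embedding followed by
    UFF relaxation; deterministic given the seed.  Heavy-atom coordinates."""
    mol = Chem.AddHs(graph_to_mol(graph))
    last_seed = seed
    for attempt in range(max_attempts):
        last_seed = int(seed + 1000 * attempt)
        params = AllChem.ETKDGv3()
        params.randomSeed = last_seed
        if AllChem.EmbedMolecule(mol, params) == 0:
            try:
                AllChem.UFFOptimizeMolecule(mol)
            except Exception:
                pass  # an unrelaxed embedding is still a valid conformer
            mol_noh = Chem.RemoveHs(mol)
            return np.array(mol_noh.GetConformer().GetPositions(), dtype=float)
    raise DockingError(
        f"3D embedding failed after {max_attempts} attempts (last seed {last_seed})"
    )


def init_pose(
    conformer: np.ndarray,
    graph: LigandGraph,
    pocket: PocketStructure,
    seed,
    config: DockConfig | None = None,
) -> np.ndarray:
    """Randomize torsions (uniform on (-pi, pi]), rotate uniformly over SO(3),
    and center the ligand at the pocket centroid plus Gaussian noise."""
    config = config or DockConfig()
    if pocket.n_atoms == 0:
        raise ValueError("pocket has no atoms")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    torsions = rng.uniform(-np.pi, np.pi, size=graph.n_torsions)
    rotation = random_rotation_vector(rng)
    shaped = apply_pose(
        conformer, graph, PoseParams(np.zeros(3), rotation, torsions)
    )
    offset = rng.normal(0.0, config.init_translation_sigma, size=3)
    return shaped + (pocket.centroid - centroid(shaped)) + offset


def minimize_pose(
    init: np.ndarray,
    graph: LigandGraph,
    pocket: PocketStructure | None = None,
    coeffs: ScoreCoefficients | None = None,
    basis: RBFBasis | None = None,
    config: DockConfig | None = None,
    objective=None,
) -> tuple[np.ndarray, float, RestartInfo]:
    """L-BFGS over pose parameters starting from zero params relative to
    ``init``.  ``objective`` may override the learned score (e.g. the analytic
    oracle); it must map a parameter vector to ``(score, gradient)``."""
    config = config or DockConfig()
    if objective is None:
        if pocket is None or coeffs is None:
            raise ValueError("either an objective or (pocket, coeffs) is required")
        basis = basis or RBFBasis()
        objective = PoseObjective(init, graph, pocket, coeffs, basis)
    x0 = np.zeros(6 + graph.n_torsions)
    f0, _ = objective(x0)
    trace = [float(f0)]

    def callback(xk):
        trace.append(float(objective(xk)[0]))

    res = scipy_minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        callback=callback,
        options={
            "maxiter": config.max_iterations,
            "maxcor": config.history_size,
            "ftol": config.tolerance,
            "gtol": config.tolerance,
        },
    )
    final_params = PoseParams.from_vector(res.x)
    final_score = float(res.fun)
    failed = not np.isfinite(final_score)
    if not failed and final_score > f0:  # line-search safeguard; keep the start
        final_params = PoseParams.from_vector(x0)
        final_score = float(f0)
    pose = apply_pose(init, graph, final_params)
    info = RestartInfo(
        seed=-1,
        iterations=int(res.nit),
        initial_score=float(f0),
        final_score=final_score,
        score_trace=trace,
        failed=failed,
    )
    return pose, final_score, info


def dock(
    graph: LigandGraph,
    pocket: PocketStructure,
    model=None,
    coeffs: ScoreCoefficients | None = None,
    basis: RBFBasis | None = None,
    config: DockConfig | None = None,
) -> DockResult:
    """Full docking run.  The encoder is invoked exactly once; each restart
    draws an independent initialization and is minimized separately."""
    config = config or DockConfig()
    basis = basis or RBFBasis()
    n_encoder_calls = 0
    if coeffs is None:
        if model is None:
            raise ValueError("either a trained model or precomputed coefficients is required")
        coeffs = model.encode(graph, pocket)
        n_encoder_calls = 1
    conformer = generate_conformer(graph, seed=config.seed)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_restarts)
    poses, scores, restarts = [], [], []
    n_failed = 0
    for k, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        init = init_pose(conformer, graph, pocket, rng, config)
        pose, score, info = minimize_pose(
            init, graph, pocket, coeffs, basis, config
        )
        info.seed = k
        restarts.append(info)
        if info.failed:
            n_failed += 1
            continue
        poses.append(pose)
        scores.append(score)
    if not poses:
        raise DockingError("all docking restarts failed (non-finite scores)")
    best = int(np.argmin(scores))
    return DockResult(
        poses=poses,
        scores=scores,
        best_index=best,
        restarts=restarts,
        n_failed=n_failed,
        n_encoder_calls=n_encoder_calls,
    )
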