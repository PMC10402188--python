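"""Synthetic toy complexes and oracle scoring coefficients.

These fixtures make every stage of the pipeline testable without any
external dataset: a small ligand (from a SMILES template) is embedded in 3D
and surrounded by an artificial shell of "residues" whose heavy atoms sit at
a controlled radius from the ligand centroid.  They are geometric test
scaffolds, not physically realistic binding sites.

:func:`make_oracle_coefficients` fits the RBF scoring coefficients by ridge
regression so that the predicted per-atom distances approximate the true
distance to the crystal pose over a cloud of perturbed poses.  Docking with
these coefficients validates the scoring function and the L-BFGS stack
end to end without any learned weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .docker import generate_conformer
from .molio import (
    STANDARD_AA,
    LigandGraph,
    PocketStructure,
    pocket_from_arrays,
    write_poses,
    read_ligand,
)
from .noiser import NoiseSchedule, sigma_at
from .posemath import PoseParams, apply_pose, centroid, random_rotation_vector
from .scorer import RBFBasis, ScoreCoefficients, pair_features

__all__ = [
    "FixtureSpec",
    "ToyComplex",
    "LIGAND_TEMPLATES",
    "make_toy_complex",
    "make_oracle_coefficients",
    "write_fixture_files",
]

LIGAND_TEMPLATES = {
    "ethanol": "CCO",       # 0 torsions
    "benzene": "c1ccccc1",  # 0 torsions, 12-fold symmetric
    "butane": "CCCC",       # 1 torsion
    "pentane": "CCCCC",     # 2 torsions
    "diglyme_core": "COCCOC",  # 3 torsions
    "acetamide_n_methyl": "CC(=O)NC",  # amide bond, 0 torsions
}

_POCKET_ELEMENTS = ("C", "C", "C", "N", "O", "S")  # carbon-rich, protein-like mix


@dataclass(frozen=True)
class FixtureSpec:
    ligand: str = "butane"       # template name or raw SMILES
    n_residues: int = 8
    radius: float = 6.0          # A, shell radius around the ligand centroid
    atoms_per_residue: int = 4   # incl. the alpha-carbon
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 1:
            raise ValueError("need at least one residue")


@dataclass
class ToyComplex:
    name: str
    smiles: str
    graph: LigandGraph
    crystal: np.ndarray
    pocket: PocketStructure


def make_toy_complex(spec: FixtureSpec) -> ToyComplex:
    """Deterministic synthetic complex.

    All pocket heavy atoms (alpha-carbons included) lie on a shell of
    ``radius`` +/- 0.5 A around the ligand centroid; residues get plausible
    amino-acid classes.  The embedded, force-field-relaxed ligand pose is the
    stored crystal pose.
    """
    smiles = LIGAND_TEMPLATES.get(spec.ligand, spec.ligand)
    graph, _ = read_ligand(smiles, format="smiles")
    crystal = generate_conformer(graph, seed=spec.seed)
    crystal = crystal - centroid(crystal)  # shell centered at the origin
    rng = np.random.default_rng(spec.seed)
    residue_classes, ca_coords = [], []
    atom_elements, atom_classes, atom_res_idx, atom_coords = [], [], [], []
    for ri in range(spec.n_residues):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        aa = str(rng.choice(STANDARD_AA))
        residue_classes.append(aa)
        for ai in range(spec.atoms_per_residue):
            if ai == 0:
                direction = u
                element = "C"  # the alpha-carbon
            else:
                direction = u + 0.25 * rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                element = str(rng.choice(_POCKET_ELEMENTS))
            pos = direction * (spec.radius + rng.uniform(-0.45, 0.45))
            if ai == 0:
                ca_coords.append(pos)
            atom_elements.append(element)
            atom_classes.append(aa)
            atom_res_idx.append(ri)
            atom_coords.append(pos)
    pocket = pocket_from_arrays(
        residue_classes, np.array(ca_coords), atom_elements,
        atom_classes, atom_res_idx, np.array(atom_coords),
    )
    name = spec.ligand if spec.ligand in LIGAND_TEMPLATES else "custom"
    return ToyComplex(name=name, smiles=smiles, graph=graph,
                      crystal=crystal, pocket=pocket)


# ---------------------------------------------------------------------------
# oracle coefficients
# ---------------------------------------------------------------------------

def _perturbed_poses(
    crystal: np.ndarray,
    graph: LigandGraph,
    n_samples: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Pose cloud covering both small perturbations (graded noise levels)
    and fully randomized placements, mirroring the docking initializer."""
    schedule = NoiseSchedule()
    poses = []
    for s in range(n_samples):
        if s % 2 == 0:  # graded severity, like the training noiser
            t = 1 + s % schedule.timesteps
            params = PoseParams(
                translation=rng.normal(0, sigma_at(schedule, t, "translation"), 3),
                rotation=rng.normal(0, sigma_at(schedule, t, "rotation"), 3),
                torsions=rng.normal(0, sigma_at(schedule, t, "torsion"), graph.n_torsions),
            )
        else:  # fully random, like a docking restart
            params = PoseParams(
                translation=rng.normal(0, schedule.sigma_max_translation, 3),
                rotation=random_rotation_vector(rng),
                torsions=rng.uniform(-np.pi, np.pi, graph.n_torsions),
            )
        poses.append(apply_pose(crystal, graph, params))
    return poses


def make_oracle_coefficients(
    crystal: np.ndarray,
    graph: LigandGraph,
    pocket: PocketStructure,
    basis: RBFBasis | None = None,
    n_samples: int = 200,
    ridge: float = 1e-2,
    seed: int = 0,
) -> ScoreCoefficients:
    """Least-squares fit of C so the scoring function approximates the true
    per-atom distance to the crystal pose.

    The bias ``beta`` is set to the mean target distance, so C regresses the
    *deviation* from that baseline: a pose that drifts outside the sampled
    cloud (all RBF activations -> 0) then scores the unattractive baseline
    rather than zero, which would otherwise hand the minimizer a spurious
    far-field optimum.  Solved per ligand atom in the dual (kernel) form
    with a ridge penalty scaled by the mean kernel diagonal; the fairly
    strong default keeps the interpolant smooth between samples, which
    matters more for minimization than the last digit of fit residual.  An
    ill-conditioned system (e.g. an all-zero perturbation set) triggers a
    warning and a stronger ridge.  The fit residual (RMS over samples and
    atoms) is stored in ``info``.
    """
    basis = basis or RBFBasis()
    crystal = np.asarray(crystal, dtype=float)
    rng = np.random.default_rng(seed)
    poses = _perturbed_poses(crystal, graph, n_samples, rng)
    L = graph.heavy_atom_count
    n_partner = L + pocket.n_atoms
    feats = np.stack([pair_features(p, pocket, basis) for p in poses])  # (S, L, J, K)
    targets = np.stack(
        [np.linalg.norm(p - crystal, axis=1) for p in poses]
    )  # (S, L)
    beta = float(targets.mean())
    if float(np.std(targets)) < 1e-9:
        warnings.warn(
            "degenerate perturbation set (no pose variance); the ridge solve "
            "falls back to the constant baseline",
            RuntimeWarning,
            stacklevel=2,
        )
    C = np.zeros((L, n_partner, basis.n_centers))
    residuals = []
    for i in range(L):
        A = feats[:, i].reshape(n_samples, -1)  # (S, F)
        y = targets[:, i] - beta
        K = A @ A.T
        lam = ridge * max(np.mean(np.diag(K)), 1e-12)
        for attempt in range(6):
            try:
                alpha = np.linalg.solve(K + lam * np.eye(n_samples), y)
                break
            except np.linalg.LinAlgError:
                lam *= 1e3
        else:
            raise np.linalg.LinAlgError("oracle coefficient fit failed to converge")
        if attempt > 0:
            warnings.warn(
                f"ill-conditioned oracle fit for atom {i}; ridge raised to {lam:.2e}",
                RuntimeWarning,
                stacklevel=2,
            )
        ci = A.T @ alpha
        C[i] = ci.reshape(n_partner, basis.n_centers)
        residuals.append(np.sqrt(np.mean((A @ ci - y) ** 2)))
    return ScoreCoefficients(
        C=C,
        beta=beta,
        info={"fit_rms_residual": float(np.mean(residuals)), "n_samples": n_samples},
    )


# ---------------------------------------------------------------------------
# on-disk fixtures (PDB / SDF / manifests)
# ---------------------------------------------------------------------------

def _pocket_to_pdb(pocket: PocketStructure, path) -> None:
    import biotite.structure as struc
    from biotite.structure.io import pdb as bpdb

    n = pocket.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(pocket.atom_coords, dtype=np.float32)
    counters: dict[int, int] = {}
    for k in range(n):
        ri = int(pocket.atom_residue_index[k])
        counters[ri] = counters.get(ri, 0) + 1
        el = pocket.atom_elements[k]
        first_in_res = counters[ri] == 1
        arr.chain_id[k] = "A"
        arr.res_id[k] = ri + 1
        arr.res_name[k] = pocket.atom_residue_classes[k]
        arr.atom_name[k] = "CA" if first_in_res else f"{el}{counters[ri]}"
        arr.element[k] = el
        arr.hetero[k] = False
    pdb_file = bpdb.PDBFile()
    bpdb.set_structure(pdb_file, arr)
    pdb_file.write(str(path))


def write_fixture_files(complexes: list[ToyComplex], out_dir) -> dict[str, Path]:
    """Write PDB/SDF files plus benchmark and training manifests.

    Returns the manifest paths.  The crystal pose doubles as the reference
    ligand defining the pocket.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bench_rows, train_rows = [], []
    for idx, cx in enumerate(complexes):
        stem = f"{idx:02d}_{cx.name}"
        pdb = f"{stem}_pocket.pdb"
        sdf = f"{stem}_crystal.sdf"
        _pocket_to_pdb(cx.pocket, out_dir / pdb)
        write_poses(cx.graph, [cx.crystal], [0.0], out_dir / sdf)
        bench_rows.append(
            {
                "pocket_id": stem,
                "ligand_id": cx.name,
                "receptor_pdb": pdb,
                "ref_ligands_sdf": sdf,
                "ligand": sdf,
                "crystal_sdf": sdf,
            }
        )
        train_rows.append({"name": stem, "ligand_sdf": sdf, "pocket_pdb": pdb})
    bench = out_dir / "manifest_benchmark.csv"
    trainm = out_dir / "manifest_train.csv"
    pd.DataFrame(bench_rows).to_csv(bench, index=False)
    pd.DataFrame(train_rows).to_csv(trainm, index=False)
    return {"benchmark": bench, "train": trainm}
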