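"""Cross-docking evaluation: RMSD success rates at 2 A and 5 A.

A pose counts as correct when its (symmetry-corrected) RMSD to the crystal
pose is strictly below the threshold.  Because benchmark sets hold very
different numbers of ligands per pocket, accuracy is reported both pooled
over all records (unnormalized) and as the unweighted mean of per-pocket
accuracies (normalized).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .docker import DockConfig, dock
from .molio import PocketDefinition, extract_pocket, filter_pocket, read_ligand, read_sdf_coords
from .posemath import rmsd
from .scorer import RBFBasis

__all__ = ["EvalRecord", "EvalReport", "evaluate", "run_benchmark"]

DEFAULT_THRESHOLDS = (2.0, 5.0)  # A


@dataclass(frozen=True)
class EvalRecord:
    pocket_id: str
    ligand_id: str
    best_rmsd: float  # A, best-scored pose vs crystal

    def __post_init__(self):
        if not self.pocket_id:
            raise ValueError("pocket_id must be non-empty")
        if self.best_rmsd < 0:
            raise ValueError("RMSD must be non-negative")


@dataclass
class EvalReport:
    thresholds: tuple[float, ...]
    per_pocket: dict[str, dict[float, float]]       # pocket -> threshold -> accuracy
    normalized: dict[float, float]                  # unweighted mean over pockets
    unnormalized: dict[float, float]                # pooled fraction
    counts: dict[str, int]                          # records per pocket
    n_records: int = 0
    n_skipped: int = 0
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "thresholds": list(self.thresholds),
            "per_pocket": {p: {str(t): v for t, v in d.items()}
                           for p, d in self.per_pocket.items()},
            "normalized": {str(t): v for t, v in self.normalized.items()},
            "unnormalized": {str(t): v for t, v in self.unnormalized.items()},
            "counts": dict(self.counts),
            "n_records": self.n_records,
            "n_skipped": self.n_skipped,
            "skipped": [list(s) for s in self.skipped],
        }


def evaluate(records: list[EvalRecord], thresholds=DEFAULT_THRESHOLDS) -> EvalReport:
    """Aggregate per-record RMSDs into normalized / unnormalized accuracies."""
    if not records:
        raise ValueError("no evaluation records")
    thresholds = tuple(float(t) for t in thresholds)
    df = pd.DataFrame(
        {
            "pocket": [r.pocket_id for r in records],
            "rmsd": [r.best_rmsd for r in records],
        }
    )
    per_pocket: dict[str, dict[float, float]] = {}
    for pocket, grp in df.groupby("pocket", sort=True):
        per_pocket[pocket] = {
            t: float((grp["rmsd"] < t).mean()) for t in thresholds
        }
    normalized = {
        t: float(np.mean([per_pocket[p][t] for p in per_pocket])) for t in thresholds
    }
    unnormalized = {t: float((df["rmsd"] < t).mean()) for t in thresholds}
    counts = {p: int(len(g)) for p, g in df.groupby("pocket", sort=True)}
    return EvalReport(
        thresholds=thresholds,
        per_pocket=per_pocket,
        normalized=normalized,
        unnormalized=unnormalized,
        counts=counts,
        n_records=len(records),
    )


def run_benchmark(
    manifest,
    model=None,
    coefficients_provider=None,
    dock_config: DockConfig | None = None,
    definition: PocketDefinition | None = None,
    basis: RBFBasis | None = None,
    thresholds=DEFAULT_THRESHOLDS,
    records_csv=None,
) -> tuple[EvalReport, pd.DataFrame]:
    """Dock every manifest row and aggregate success rates.

    Manifest CSV columns: ``pocket_id``, ``ligand_id``, ``receptor_pdb``,
    ``ref_ligands_sdf`` (reference poses defining the pocket, union over
    records), ``ligand`` (SMILES or an SDF path), ``crystal_sdf`` (ground
    truth).  Paths resolve relative to the manifest.

    ``coefficients_provider(graph, pocket, row) -> ScoreCoefficients`` can
    replace the trained model (e.g. with fitted oracle coefficients).  Rows
    that fail to resolve or fail the pocket filters are skipped with a
    logged reason, not counted as docking failures.
    """
    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    if df.empty:
        raise ValueError(f"empty benchmark manifest {manifest}")
    dock_config = dock_config or DockConfig()
    definition = definition or PocketDefinition()
    basis = basis or RBFBasis()
    records: list[EvalRecord] = []
    rows_out = []
    skipped: list[tuple[str, str]] = []
    for _, row in df.iterrows():
        rid = f"{row['pocket_id']}/{row['ligand_id']}"
        try:
            refs = read_sdf_coords(manifest.parent / str(row["ref_ligands_sdf"]))
            ligand = str(row["ligand"])
            if ligand.endswith(".sdf"):
                graph, _ = read_ligand(str(manifest.parent / ligand), format="sdf")
            else:
                graph, _ = read_ligand(ligand, format="smiles")
            _, crystal = read_ligand(
                str(manifest.parent / str(row["crystal_sdf"])), format="sdf"
            )
            if crystal is None:
                raise ValueError("crystal SDF lacks 3D coordinates")
            pocket = extract_pocket(
                manifest.parent / str(row["receptor_pdb"]), refs, definition
            )
            verdict = filter_pocket(pocket, definition)
            if not verdict:
                skipped.append((rid, f"pocket filter: {verdict.reason}"))
                continue
            if coefficients_provider is not None:
                coeffs = coefficients_provider(graph, pocket, row)
                result = dock(graph, pocket, coeffs=coeffs, basis=basis, config=dock_config)
            else:
                if model is None:
                    raise ValueError("neither model nor coefficients_provider given")
                result = dock(graph, pocket, model=model, basis=basis, config=dock_config)
            best_rmsd = rmsd(result.best_pose, crystal, graph, symmetry_corrected=True)
            oracle_rmsd = min(
                rmsd(p, crystal, graph, symmetry_corrected=True) for p in result.poses
            )
            records.append(EvalRecord(str(row["pocket_id"]), str(row["ligand_id"]), best_rmsd))
            rows_out.append(
                {
                    "pocket_id": row["pocket_id"],
                    "ligand_id": row["ligand_id"],
                    "best_rmsd": best_rmsd,
                    "oracle_best_rmsd": oracle_rmsd,
                    "best_score": result.best_score,
                    "n_failed_restarts": result.n_failed,
                }
            )
        except (ValueError, OSError, KeyError) as err:
            skipped.append((rid, str(err)))
    if not records:
        raise ValueError(
            f"no benchmark row could be evaluated; skips: {skipped}"
        )
    report = evaluate(records, thresholds)
    report.n_skipped = len(skipped)
    report.skipped = skipped
    out_df = pd.DataFrame(rows_out)
    if records_csv is not None:
        out_df.to_csv(records_csv, index=False)
    return report, out_df
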