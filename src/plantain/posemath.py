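"""Pose parameterization and geometry.

A pose is parameterized by a translation vector (A), an axis-angle rotation
vector (radians), and one dihedral update per rotatable bond.  Applying a pose
to a reference conformation proceeds torsions first (each rotating only its
moving-side atoms about the bond axis), then the rigid rotation about the
reference centroid, then the translation.  This fixed order makes round trips
well defined.

Two implementations of the transform exist: a plain NumPy one (fast path used
by the noiser and docking initializer) and an autodiff one used to obtain
exact score gradients; a test pins them against each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.transform import Rotation

from . import autodiff as ad
from .molio import LigandGraph

__all__ = [
    "PoseParams",
    "centroid",
    "apply_pose",
    "apply_pose_tensors",
    "invert_pose",
    "rmsd",
    "graph_automorphisms",
    "random_rotation_vector",
]

Conformation = np.ndarray  # (n_heavy_atoms, 3) in A


@dataclass
class PoseParams:
    """Translation (A) + axis-angle rotation + torsions (radians)."""

    translation: np.ndarray  # (3,)
    rotation: np.ndarray     # (3,) direction = axis, magnitude = angle
    torsions: np.ndarray     # (n_rotatable_bonds,)

    def __post_init__(self):
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3)
        self.torsions = np.asarray(self.torsions, dtype=float).reshape(-1)

    @classmethod
    def zero(cls, n_torsions: int) -> "PoseParams":
        return cls(np.zeros(3), np.zeros(3), np.zeros(n_torsions))

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.translation, self.rotation, self.torsions])

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "PoseParams":
        vec = np.asarray(vec, dtype=float)
        return cls(vec[:3], vec[3:6], vec[6:])

    @property
    def n_dof(self) -> int:
        return 6 + len(self.torsions)


def centroid(coords: Conformation) -> np.ndarray:
    return np.asarray(coords, dtype=float).mean(axis=0)


def _check_dims(ref: Conformation, graph: LigandGraph, params: PoseParams) -> np.ndarray:
    ref = np.asarray(ref, dtype=float)
    if ref.shape != (graph.heavy_atom_count, 3):
        raise ValueError(
            f"conformation shape {ref.shape} does not match graph "
            f"({graph.heavy_atom_count} heavy atoms)"
        )
    if len(params.torsions) != graph.n_torsions:
        raise ValueError(
            f"{len(params.torsions)} torsion values for {graph.n_torsions} rotatable bonds"
        )
    return ref


def apply_pose(ref: Conformation, graph: LigandGraph, params: PoseParams) -> Conformation:
    """Apply torsions, then the rigid rotation about centroid(ref), then the
    translation.  Bond lengths and non-torsion angles are preserved."""
    ref = _check_dims(ref, graph, params)
    coords = ref.copy()
    for rb, tau in zip(graph.rotatable_bonds, params.torsions):
        if tau == 0.0:
            continue
        pivot = coords[rb.fixed_atom]
        axis = coords[rb.moving_atom] - pivot
        axis = axis / np.linalg.norm(axis)
        rot = Rotation.from_rotvec(axis * tau).as_matrix()
        idx = list(rb.moving_atoms)
        coords[idx] = pivot + (coords[idx] - pivot) @ rot.T
    c = centroid(ref)
    rot = Rotation.from_rotvec(params.rotation).as_matrix()
    return (coords - c) @ rot.T + c + params.translation


def apply_pose_tensors(
    ref: Conformation,
    graph: LigandGraph,
    translation: ad.Tensor,
    rotation: ad.Tensor,
    torsions: ad.Tensor,
) -> ad.Tensor:
    """Autodiff version of :func:`apply_pose` (same semantics)."""
    ref = np.asarray(ref, dtype=float)
    n = ref.shape[0]
    coords = ad.as_tensor(ref)
    for k, rb in enumerate(graph.rotatable_bonds):
        pivot = coords[rb.fixed_atom]          # (3,)
        axis = coords[rb.moving_atom] - pivot  # (3,)
        unit = axis / ad.sqrt(ad.tsum(axis * axis))
        rotvec = unit * torsions[k]
        shifted = coords - ad.reshape(pivot, (1, 3))
        rotated = ad.rotate_rotvec(shifted, rotvec) + ad.reshape(pivot, (1, 3))
        mask = np.zeros((n, 1), dtype=bool)
        mask[list(rb.moving_atoms)] = True
        coords = ad.where(mask, rotated, coords)
    c = ref.mean(axis=0)
    rotated = ad.rotate_rotvec(coords - c, rotation)
    return rotated + c + ad.reshape(translation, (1, 3))


def invert_pose(params: PoseParams, ref: Conformation, graph: LigandGraph) -> PoseParams:
    """Parameters that undo ``params``: applying them to
    ``apply_pose(ref, params)`` recovers ``ref``.

    Torsion rotations about distinct bonds commute (moving-side sets are
    nested or disjoint), so negated torsions invert the torsional part; the
    rigid part is inverted in closed form accounting for the two different
    rotation centers.
    """
    ref = _check_dims(ref, graph, params)
    moved = apply_pose(ref, graph, params)
    c = centroid(ref)
    c_prime = centroid(moved)
    rot = Rotation.from_rotvec(params.rotation).as_matrix()
    t_inv = c - c_prime + rot.T @ (c_prime - c - params.translation)
    return PoseParams(
        translation=t_inv,
        rotation=-params.rotation,
        torsions=-params.torsions,
    )


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def graph_automorphisms(graph: LigandGraph, cap: int = 10_000) -> list[np.ndarray]:
    """Feature-preserving graph automorphisms (at most ``cap``), identity first."""
    g = nx.Graph()
    for i, a in enumerate(graph.atoms):
        g.add_node(i, feat=(a.element, a.formal_charge, a.hybridization,
                            a.n_hydrogens, a.aromatic))
    for b in graph.bonds:
        g.add_edge(b.i, b.j, order=b.order)
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g, g,
        node_match=lambda x, y: x["feat"] == y["feat"],
        edge_match=lambda x, y: x["order"] == y["order"],
    )
    n = graph.heavy_atom_count
    perms = [np.arange(n)]
    seen = {tuple(range(n))}
    for mapping in matcher.isomorphisms_iter():
        perm = tuple(mapping[i] for i in range(n))
        if perm not in seen:
            seen.add(perm)
            perms.append(np.array(perm))
        if len(perms) >= cap:
            break
    return perms


def rmsd(
    a: Conformation,
    b: Conformation,
    graph: LigandGraph | None = None,
    symmetry_corrected: bool = False,
    automorphism_cap: int = 10_000,
) -> float:
    """Root-mean-square deviation in A, without realignment.

    With ``symmetry_corrected`` the minimum over feature-preserving graph
    automorphisms is returned (enumeration capped; the identity mapping is
    always included).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"conformation shapes differ: {a.shape} vs {b.shape}")

    def _plain(x, y):
        return float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1))))

    if not symmetry_corrected or graph is None:
        return _plain(a, b)
    best = np.inf
    for perm in graph_automorphisms(graph, cap=automorphism_cap):
        best = min(best, _plain(a, b[perm]))
    return best


def random_rotation_vector(rng: np.random.Generator) -> np.ndarray:
    """Axis-angle vector of a rotation drawn uniformly from SO(3)
    (via a uniformly random unit quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return Rotation.from_quat(q).as_rotvec()
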