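"""The RBF pose-scoring function.

Given coefficients ``C[i, j, k]`` (ligand atom i, partner atom j, Gaussian
basis k) and a scalar bias ``beta``, the predicted distance of ligand atom i
to its true position is

    D_i = sum_j sum_k C[i, j, k] * exp(-(d_ij - c_k)^2 / sigma^2) + beta

where ``d_ij`` runs over all ligand-ligand (j != i) and ligand-pocket-atom
distances, and the 24 reference distances ``c_k`` are evenly spaced from 0
with spacing sigma = 32/24 A.  The global pose score is the mean of the D_i;
no clamping is applied, so negative predictions are permitted.

Gradients of the score with respect to pose parameters (translation, rigid
rotation, torsions) are computed exactly by backpropagating through the pose
transform; they drive the L-BFGS minimizer in :mod:`plantain.docker`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .molio import LigandGraph, PocketStructure
from .posemath import PoseParams, apply_pose_tensors

__all__ = [
    "RBFBasis",
    "ScoreCoefficients",
    "pair_distances",
    "pair_features",
    "predict_atom_distances",
    "score_pose",
    "score_gradient",
    "PoseObjective",
    "OracleObjective",
]


@dataclass(frozen=True)
class RBFBasis:
    """Gaussian radial basis over interatomic distances."""

    n_centers: int = 24
    d_max: float = 32.0  # A

    @property
    def sigma(self) -> float:
        return self.d_max / self.n_centers  # = 32/24 A by default

    @property
    def centers(self) -> np.ndarray:
        # evenly spaced from 0 with spacing equal to sigma
        return np.arange(self.n_centers) * self.sigma

    def expand(self, d: np.ndarray) -> np.ndarray:
        """exp(-(d - c_k)^2 / sigma^2) along a trailing basis axis."""
        d = np.asarray(d, dtype=float)
        return np.exp(-((d[..., None] - self.centers) ** 2) / self.sigma**2)


@dataclass
class ScoreCoefficients:
    """C[i, j, k] over (ligand atom, ligand+pocket partner atom, basis)."""

    C: np.ndarray       # (L, L + P, K)
    beta: float = 0.0
    info: dict = field(default_factory=dict, compare=False)

    @property
    def n_ligand_atoms(self) -> int:
        return self.C.shape[0]

    def validate(self, n_ligand: int, n_pocket: int, basis: RBFBasis) -> None:
        expected = (n_ligand, n_ligand + n_pocket, basis.n_centers)
        if self.C.shape != expected:
            raise ValueError(f"coefficient shape {self.C.shape}, expected {expected}")
        if not np.all(np.isfinite(self.C)) or not np.isfinite(self.beta):
            raise ValueError("coefficients must be finite")


def _self_pair_mask(n_ligand: int, n_partner: int) -> np.ndarray:
    mask = np.zeros((n_ligand, n_partner), dtype=bool)
    idx = np.arange(n_ligand)
    mask[idx, idx] = True
    return mask


def pair_distances(coords: np.ndarray, pocket: PocketStructure) -> np.ndarray:
    """(L, L+P) distances from ligand atoms to ligand+pocket partner atoms.
    Self pairs hold 0 and are ignored by the scoring sums."""
    coords = np.asarray(coords, dtype=float)
    partners = np.concatenate([coords, pocket.atom_coords], axis=0)
    diff = coords[:, None, :] - partners[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def pair_features(
    coords: np.ndarray,
    pocket: PocketStructure,
    basis: RBFBasis,
    cutoff: float | None = None,
) -> np.ndarray:
    """RBF expansion Phi[i, j, k] of all pair distances, self pairs zeroed.

    ``cutoff`` (A) optionally zeroes pairs beyond it; Gaussian decay makes a
    40 A cutoff numerically irrelevant, so it is off by default.
    """
    d = pair_distances(coords, pocket)
    phi = basis.expand(d)
    mask = _self_pair_mask(d.shape[0], d.shape[1])
    phi[mask] = 0.0
    if cutoff is not None:
        phi[d > cutoff] = 0.0
    return phi


def predict_atom_distances(
    coords: np.ndarray,
    pocket: PocketStructure,
    coeffs: ScoreCoefficients,
    basis: RBFBasis,
    cutoff: float | None = None,
) -> np.ndarray:
    """Per-atom predicted distance to the true position (A-scale)."""
    coords = np.asarray(coords, dtype=float)
    coeffs.validate(coords.shape[0], pocket.n_atoms, basis)
    phi = pair_features(coords, pocket, basis, cutoff=cutoff)
    return np.einsum("ijk,ijk->i", coeffs.C, phi) + coeffs.beta


def score_pose(
    coords: np.ndarray,
    pocket: PocketStructure,
    coeffs: ScoreCoefficients,
    basis: RBFBasis,
    cutoff: float | None = None,
) -> float:
    """Mean predicted per-atom distance; the quantity L-BFGS minimizes."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] == 0:
        raise ValueError("cannot score an empty ligand")
    return float(predict_atom_distances(coords, pocket, coeffs, basis, cutoff).mean())


# ---------------------------------------------------------------------------
# differentiable objectives over pose parameters
# ---------------------------------------------------------------------------

def _leaf_grad(leaf) -> np.ndarray:
    """Gradient of a leaf tensor, zeros when it never entered the graph
    (e.g. the empty torsion vector of a rigid ligand)."""
    return leaf.grad if leaf.grad is not None else np.zeros_like(leaf.value)

class PoseObjective:
    """score(apply_pose(ref, params)) and its exact gradient.

    Callable on a flat parameter vector ``[t(3), r(3), torsions]``; returns
    ``(score, gradient)`` suitable for ``scipy.optimize.minimize(jac=True)``.
    """

    def __init__(
        self,
        ref: np.ndarray,
        graph: LigandGraph,
        pocket: PocketStructure,
        coeffs: ScoreCoefficients,
        basis: RBFBasis,
    ):
        self.ref = np.asarray(ref, dtype=float)
        self.graph = graph
        self.pocket = pocket
        self.coeffs = coeffs
        self.basis = basis
        coeffs.validate(self.ref.shape[0], pocket.n_atoms, basis)
        L = self.ref.shape[0]
        P = pocket.n_atoms
        self._mask3 = _self_pair_mask(L, L + P)[:, :, None]
        self._partner_pocket = np.asarray(pocket.atom_coords, dtype=float)

    @property
    def n_dof(self) -> int:
        return 6 + self.graph.n_torsions

    def _coords_tensor(self, vec: np.ndarray):
        vec = np.asarray(vec, dtype=float)
        t = ad.Tensor(vec[:3], requires_grad=True)
        r = ad.Tensor(vec[3:6], requires_grad=True)
        tau = ad.Tensor(vec[6:], requires_grad=True)
        coords = apply_pose_tensors(self.ref, self.graph, t, r, tau)
        return coords, (t, r, tau)

    def __call__(self, vec: np.ndarray) -> tuple[float, np.ndarray]:
        coords, leaves = self._coords_tensor(vec)
        L = self.ref.shape[0]
        partners = ad.concat([coords, ad.as_tensor(self._partner_pocket)], axis=0)
        diff = ad.reshape(coords, (L, 1, 3)) - ad.reshape(partners, (1, -1, 3))
        sq = ad.tsum(diff * diff, axis=2)
        # keep sqrt differentiable on the (masked-out) self pairs
        sq_safe = ad.where(self._mask3[:, :, 0], np.ones_like(sq.value), sq)
        d = ad.sqrt(sq_safe)
        dev = ad.reshape(d, (L, -1, 1)) - self.basis.centers
        phi = ad.exp(dev * dev * (-1.0 / self.basis.sigma**2))
        term = ad.where(self._mask3, np.zeros(1), self.coeffs.C * phi)
        d_hat = ad.tsum(term, axis=(1, 2)) + self.coeffs.beta
        score = ad.tmean(d_hat)
        ad.backward(score)
        grad = np.concatenate([_leaf_grad(leaf) for leaf in leaves])
        return float(score.value), grad


class OracleObjective:
    """Analytic oracle score: mean per-atom distance to the crystal pose.

    A perfect distance predictor, used to validate the pose math and the
    L-BFGS minimization stack independently of any learned weights.
    """

    def __init__(self, ref: np.ndarray, graph: LigandGraph, crystal: np.ndarray):
        self.ref = np.asarray(ref, dtype=float)
        self.graph = graph
        self.crystal = np.asarray(crystal, dtype=float)

    @property
    def n_dof(self) -> int:
        return 6 + self.graph.n_torsions

    def __call__(self, vec: np.ndarray) -> tuple[float, np.ndarray]:
        vec = np.asarray(vec, dtype=float)
        t = ad.Tensor(vec[:3], requires_grad=True)
        r = ad.Tensor(vec[3:6], requires_grad=True)
        tau = ad.Tensor(vec[6:], requires_grad=True)
        coords = apply_pose_tensors(self.ref, self.graph, t, r, tau)
        diff = coords - self.crystal
        # small floor keeps the gradient finite at the exact optimum
        dist = ad.sqrt(ad.tsum(diff * diff, axis=1) + 1e-12)
        score = ad.tmean(dist)
        ad.backward(score)
        grad = np.concatenate([_leaf_grad(x) for x in (t, r, tau)])
        return float(score.value), grad


def score_gradient(
    coords: np.ndarray,
    pocket: PocketStructure,
    coeffs: ScoreCoefficients,
    basis: RBFBasis,
    graph: LigandGraph,
    ref: np.ndarray,
    params: PoseParams,
) -> np.ndarray:
    """Exact gradient of the pose score with respect to ``params``.

    ``coords`` is accepted for interface symmetry and cross-checked against
    ``apply_pose(ref, graph, params)``.
    """
    from .posemath import apply_pose

    expected = apply_pose(ref, graph, params)
    if coords is not None and not np.allclose(coords, expected, atol=1e-8):
        raise ValueError("coords do not equal apply_pose(ref, graph, params)")
    obj = PoseObjective(ref, graph, pocket, coeffs, basis)
    _, grad = obj(params.to_vector())
    return grad
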