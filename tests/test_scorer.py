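"""Closed-form checks of the RBF scoring function and its gradients."""

import numpy as np
import pytest

from plantain.molio import pocket_from_arrays, read_ligand
from plantain.posemath import PoseParams, apply_pose
from plantain.scorer import (
    OracleObjective,
    PoseObjective,
    RBFBasis,
    ScoreCoefficients,
    predict_atom_distances,
    score_gradient,
    score_pose,
)


def single_atom_pocket(xyz):
    return pocket_from_arrays(
        ["ALA"], np.array([xyz]), ["C"], ["ALA"], [0], np.array([xyz])
    )


@pytest.fixture(scope="module")
def basis():
    return RBFBasis()


def test_basis_parameters(basis):
    assert basis.sigma == pytest.approx(32.0 / 24.0)
    assert basis.n_centers == 24
    np.testing.assert_allclose(np.diff(basis.centers), basis.sigma)
    assert basis.centers[0] == 0.0


def zero_coeffs(n_lig, n_pocket, basis, beta=0.0):
    return ScoreCoefficients(
        C=np.zeros((n_lig, n_lig + n_pocket, basis.n_centers)), beta=beta
    )


def test_bias_only(basis):
    """All C = 0: every predicted distance equals beta."""
    graph, _ = read_ligand("CCO")
    coords = np.array([[0.0, 0, 0], [1.5, 0, 0], [2.4, 1.0, 0]])
    pocket = single_atom_pocket([5.0, 0, 0])
    coeffs = zero_coeffs(3, 1, basis, beta=0.7)
    d_hat = predict_atom_distances(coords, pocket, coeffs, basis)
    np.testing.assert_allclose(d_hat, 0.7, atol=1e-12)
    assert score_pose(coords, pocket, coeffs, basis) == pytest.approx(0.7, abs=1e-9)


def test_gaussian_center_and_one_sigma_offset(basis):
    """A single active pair at d = c_5 gives exp(0); at c_5 + sigma, exp(-1)."""
    coords = np.array([[0.0, 0, 0]])
    k = 5
    for offset, expected in [(0.0, 1.0), (basis.sigma, np.exp(-1.0))]:
        pocket = single_atom_pocket([basis.centers[k] + offset, 0.0, 0.0])
        coeffs = zero_coeffs(1, 1, basis)
        coeffs.C[0, 1, k] = 1.0
        d_hat = predict_atom_distances(coords, pocket, coeffs, basis)
        assert d_hat[0] == pytest.approx(expected, abs=1e-9)
        assert score_pose(coords, pocket, coeffs, basis) == pytest.approx(
            d_hat[0], abs=1e-12
        )


def test_single_atom_ligand_score_is_d0(basis):
    coords = np.array([[0.0, 0, 0]])
    pocket = single_atom_pocket([3.0, 0, 0])
    rng = np.random.default_rng(0)
    coeffs = ScoreCoefficients(C=rng.normal(size=(1, 2, 24)), beta=0.1)
    d_hat = predict_atom_distances(coords, pocket, coeffs, basis)
    assert score_pose(coords, pocket, coeffs, basis) == pytest.approx(float(d_hat[0]))


def test_mean_over_atoms(basis):
    """Score is the arithmetic mean of per-atom predictions."""
    coords = np.array([[0.0, 0, 0], [2.0, 0, 0], [4.0, 0, 0]])
    pocket = single_atom_pocket([10.0, 0, 0])
    rng = np.random.default_rng(1)
    coeffs = ScoreCoefficients(C=rng.normal(size=(3, 4, 24)), beta=0.0)
    d_hat = predict_atom_distances(coords, pocket, coeffs, basis)
    assert score_pose(coords, pocket, coeffs, basis) == pytest.approx(float(d_hat.mean()))


def test_self_pairs_excluded(basis):
    """Diagonal ligand-ligand coefficients never contribute."""
    coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
    pocket = single_atom_pocket([40.0, 40, 40])
    coeffs = zero_coeffs(2, 1, basis)
    coeffs.C[0, 0, :] = 100.0
    coeffs.C[1, 1, :] = 100.0
    d_hat = predict_atom_distances(coords, pocket, coeffs, basis)
    np.testing.assert_allclose(d_hat, 0.0, atol=1e-9)


def test_linearity_in_coefficients(basis, butane_complex):
    cx = butane_complex
    rng = np.random.default_rng(2)
    shape = (4, 4 + cx.pocket.n_atoms, 24)
    c1, c2 = rng.normal(size=shape), rng.normal(size=shape)
    alpha = 1.7
    s1 = score_pose(cx.crystal, cx.pocket, ScoreCoefficients(C=c1), basis)
    s2 = score_pose(cx.crystal, cx.pocket, ScoreCoefficients(C=c2), basis)
    s12 = score_pose(cx.crystal, cx.pocket, ScoreCoefficients(C=alpha * c1 + c2), basis)
    assert s12 == pytest.approx(alpha * s1 + s2, abs=1e-9)


def test_rigid_motion_invariance(basis, diglyme_complex):
    """Jointly moving ligand and pocket leaves the score unchanged."""
    from scipy.spatial.transform import Rotation
    import copy

    cx = diglyme_complex
    rng = np.random.default_rng(3)
    coeffs = ScoreCoefficients(
        C=rng.normal(0, 0.1, (6, 6 + cx.pocket.n_atoms, 24)), beta=0.2
    )
    s0 = score_pose(cx.crystal, cx.pocket, coeffs, basis)
    for seed in range(10):
        r = np.random.default_rng(seed)
        rot = Rotation.from_rotvec(r.normal(size=3)).as_matrix()
        t = r.normal(0, 5, 3)
        pocket2 = copy.deepcopy(cx.pocket)
        pocket2.atom_coords = cx.pocket.atom_coords @ rot.T + t
        pocket2.ca_coords = cx.pocket.ca_coords @ rot.T + t
        s1 = score_pose(cx.crystal @ rot.T + t, pocket2, coeffs, basis)
        assert abs(s1 - s0) < 1e-6


def test_distance_cutoff_negligible(basis, butane_complex):
    cx = butane_complex
    rng = np.random.default_rng(4)
    coeffs = ScoreCoefficients(
        C=rng.uniform(-10, 10, (4, 4 + cx.pocket.n_atoms, 24)), beta=0.0
    )
    full = score_pose(cx.crystal, cx.pocket, coeffs, basis)
    cut = score_pose(cx.crystal, cx.pocket, coeffs, basis, cutoff=40.0)
    assert abs(full - cut) < 1e-5


def test_representability_of_distance_signal(basis):
    """A single pair's 24 RBFs can encode f(d) = |d - 8| to < 0.2 on [2, 20] A.

    A few reweighting passes steer the least-squares fit toward the maximum
    error (which a plain L2 fit concentrates at the kink of the target).
    """
    grid = np.linspace(2.0, 20.0, 400)
    A = basis.expand(grid)
    target = np.abs(grid - 8.0)
    w = np.ones_like(target)
    for _ in range(20):
        sw = np.sqrt(w)[:, None]
        c, *_ = np.linalg.lstsq(A * sw, target * sw[:, 0], rcond=None)
        w = np.maximum(np.abs(A @ c - target), 1e-6)
    assert np.abs(A @ c - target).max() < 0.2


def test_empty_ligand_rejected(basis):
    pocket = single_atom_pocket([1.0, 0, 0])
    with pytest.raises(ValueError):
        score_pose(np.zeros((0, 3)), pocket, zero_coeffs(0, 1, basis), basis)


def test_shape_mismatch_rejected(basis, butane_complex):
    cx = butane_complex
    bad = ScoreCoefficients(C=np.zeros((4, 7, 24)))
    with pytest.raises(ValueError):
        predict_atom_distances(cx.crystal, cx.pocket, bad, basis)


# -- gradients --------------------------------------------------------------

def finite_difference(obj, x, h=1e-5):
    fd = np.zeros_like(x)
    for i in range(len(x)):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        fd[i] = (obj(xp)[0] - obj(xm)[0]) / (2 * h)
    return fd


def test_zero_coefficients_zero_gradient(basis, butane_complex):
    cx = butane_complex
    coeffs = zero_coeffs(4, cx.pocket.n_atoms, basis, beta=1.0)
    obj = PoseObjective(cx.crystal, cx.graph, cx.pocket, coeffs, basis)
    f, g = obj(np.zeros(obj.n_dof))
    assert f == pytest.approx(1.0)
    np.testing.assert_allclose(g, 0.0, atol=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_gradient_matches_finite_differences(basis, diglyme_complex, seed):
    cx = diglyme_complex
    rng = np.random.default_rng(seed)
    coeffs = ScoreCoefficients(
        C=rng.normal(0, 0.05, (6, 6 + cx.pocket.n_atoms, 24)), beta=0.3
    )
    obj = PoseObjective(cx.crystal, cx.graph, cx.pocket, coeffs, basis)
    x = rng.normal(0, 0.3, obj.n_dof)
    _, g = obj(x)
    fd = finite_difference(obj, x)
    np.testing.assert_allclose(g, fd, rtol=1e-4, atol=1e-7)


def test_score_gradient_api(basis, butane_complex):
    cx = butane_complex
    rng = np.random.default_rng(9)
    coeffs = ScoreCoefficients(
        C=rng.normal(0, 0.05, (4, 4 + cx.pocket.n_atoms, 24)), beta=0.0
    )
    params = PoseParams(rng.normal(0, 1, 3), rng.normal(0, 0.3, 3),
                        rng.normal(0, 0.5, cx.graph.n_torsions))
    coords = apply_pose(cx.crystal, cx.graph, params)
    g = score_gradient(coords, cx.pocket, coeffs, basis, cx.graph, cx.crystal, params)
    assert g.shape == (6 + cx.graph.n_torsions,)
    with pytest.raises(ValueError):
        score_gradient(coords + 0.1, cx.pocket, coeffs, basis, cx.graph,
                       cx.crystal, params)


def test_oracle_objective_gradient(diglyme_complex):
    cx = diglyme_complex
    obj = OracleObjective(cx.crystal + 0.4, cx.graph, cx.crystal)
    rng = np.random.default_rng(7)
    x = rng.normal(0, 0.3, obj.n_dof)
    _, g = obj(x)
    fd = finite_difference(obj, x)
    np.testing.assert_allclose(g, fd, rtol=1e-4, atol=1e-7)
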