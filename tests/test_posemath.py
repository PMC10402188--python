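"""Pose transform, inversion round trips, and RMSD."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from plantain.molio import read_ligand
from plantain.posemath import (
    PoseParams,
    apply_pose,
    apply_pose_tensors,
    centroid,
    invert_pose,
    rmsd,
)
from plantain import autodiff as ad


def dihedral(p0, p1, p2, p3):
    """Standard four-point dihedral angle."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    return np.arctan2(np.dot(np.cross(b1, v), w), np.dot(v, w))


def random_params(graph, rng, t_scale=2.0, r_scale=0.8, tor_scale=1.5):
    return PoseParams(
        rng.normal(0, t_scale, 3),
        rng.normal(0, r_scale, 3),
        rng.normal(0, tor_scale, graph.n_torsions),
    )


def test_zero_params_is_identity(butane_complex):
    cx = butane_complex
    out = apply_pose(cx.crystal, cx.graph, PoseParams.zero(cx.graph.n_torsions))
    np.testing.assert_array_equal(out, cx.crystal)


def test_pure_translation(butane_complex):
    cx = butane_complex
    p = PoseParams(np.array([1.0, 0, 0]), np.zeros(3), np.zeros(cx.graph.n_torsions))
    out = apply_pose(cx.crystal, cx.graph, p)
    np.testing.assert_allclose(out - cx.crystal, np.tile([1.0, 0, 0], (4, 1)), atol=1e-12)


def test_translations_compose_additively(butane_complex):
    cx = butane_complex
    t1, t2 = np.array([1.0, -2.0, 0.5]), np.array([0.3, 0.4, -1.0])
    zero = np.zeros(cx.graph.n_torsions)
    one = apply_pose(
        apply_pose(cx.crystal, cx.graph, PoseParams(t1, np.zeros(3), zero)),
        cx.graph,
        PoseParams(t2, np.zeros(3), zero),
    )
    both = apply_pose(cx.crystal, cx.graph, PoseParams(t1 + t2, np.zeros(3), zero))
    np.testing.assert_allclose(one, both, atol=1e-12)


def test_torsion_changes_dihedral_by_pi(butane_complex):
    cx = butane_complex
    p = PoseParams(np.zeros(3), np.zeros(3), np.array([np.pi]))
    out = apply_pose(cx.crystal, cx.graph, p)
    before = dihedral(*cx.crystal[:4])
    after = dihedral(*out[:4])
    delta = np.angle(np.exp(1j * (after - before)))
    assert abs(abs(delta) - np.pi) < 1e-8
    # bond along the rotation axis is untouched
    rb = cx.graph.rotatable_bonds[0]
    assert np.isclose(
        np.linalg.norm(out[rb.fixed_atom] - out[rb.moving_atom]),
        np.linalg.norm(cx.crystal[rb.fixed_atom] - cx.crystal[rb.moving_atom]),
        atol=1e-12,
    )


def test_rigid_part_preserves_all_pairwise_distances(diglyme_complex):
    cx = diglyme_complex
    p = PoseParams(np.array([1.0, 2.0, -0.5]), np.array([0.4, -0.2, 0.9]),
                   np.zeros(cx.graph.n_torsions))
    out = apply_pose(cx.crystal, cx.graph, p)
    d0 = np.linalg.norm(cx.crystal[:, None] - cx.crystal[None], axis=2)
    d1 = np.linalg.norm(out[:, None] - out[None], axis=2)
    np.testing.assert_allclose(d0, d1, atol=1e-9)


def test_torsion_preserves_bond_lengths(diglyme_complex):
    cx = diglyme_complex
    rng = np.random.default_rng(5)
    p = PoseParams(np.zeros(3), np.zeros(3), rng.normal(0, 2.0, cx.graph.n_torsions))
    out = apply_pose(cx.crystal, cx.graph, p)
    for b in cx.graph.bonds:
        assert np.isclose(
            np.linalg.norm(out[b.i] - out[b.j]),
            np.linalg.norm(cx.crystal[b.i] - cx.crystal[b.j]),
            atol=1e-6,
        )


def test_dimension_mismatch_raises(butane_complex):
    cx = butane_complex
    with pytest.raises(ValueError):
        apply_pose(cx.crystal, cx.graph, PoseParams(np.zeros(3), np.zeros(3), np.zeros(3)))
    with pytest.raises(ValueError):
        apply_pose(cx.crystal[:2], cx.graph, PoseParams.zero(cx.graph.n_torsions))


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_invert_round_trip(diglyme_complex, seed):
    cx = diglyme_complex
    rng = np.random.default_rng(seed)
    p = random_params(cx.graph, rng)
    # keep the rotation magnitude below pi as per the inversion contract
    if np.linalg.norm(p.rotation) >= np.pi:
        p.rotation *= 0.9 * np.pi / np.linalg.norm(p.rotation)
    moved = apply_pose(cx.crystal, cx.graph, p)
    back = apply_pose(moved, cx.graph, invert_pose(p, cx.crystal, cx.graph))
    assert np.abs(back - cx.crystal).max() < 1e-6


def test_invert_trivial_cases(butane_complex):
    cx = butane_complex
    zero = PoseParams.zero(cx.graph.n_torsions)
    inv = invert_pose(zero, cx.crystal, cx.graph)
    np.testing.assert_allclose(inv.to_vector(), zero.to_vector(), atol=1e-12)
    pure_t = PoseParams(np.array([2.0, -1.0, 3.0]), np.zeros(3),
                        np.zeros(cx.graph.n_torsions))
    inv = invert_pose(pure_t, cx.crystal, cx.graph)
    np.testing.assert_allclose(inv.translation, -pure_t.translation, atol=1e-12)


def test_tensor_and_numpy_transforms_agree(diglyme_complex):
    cx = diglyme_complex
    rng = np.random.default_rng(11)
    p = random_params(cx.graph, rng)
    want = apply_pose(cx.crystal, cx.graph, p)
    got = apply_pose_tensors(
        cx.crystal, cx.graph,
        ad.Tensor(p.translation), ad.Tensor(p.rotation), ad.Tensor(p.torsions),
    ).value
    np.testing.assert_allclose(got, want, atol=1e-12)


# -- RMSD -------------------------------------------------------------------

def test_rmsd_identical_and_uniform_shift(butane_complex):
    cx = butane_complex
    assert rmsd(cx.crystal, cx.crystal) == 0.0
    shifted = cx.crystal + np.array([3.0, 0.0, 0.0])
    assert np.isclose(rmsd(cx.crystal, shifted), 3.0)


def test_rmsd_mismatch_raises(butane_complex):
    with pytest.raises(ValueError):
        rmsd(butane_complex.crystal, butane_complex.crystal[:2])


def test_benzene_sixty_degree_rotation_symmetry(benzene_complex):
    cx = benzene_complex
    coords = cx.crystal - centroid(cx.crystal)
    normal = np.linalg.svd(coords)[2][2]
    rot = Rotation.from_rotvec(normal * np.pi / 3).as_matrix()
    rotated = coords @ rot.T
    assert rmsd(coords, rotated) > 0.5
    assert rmsd(coords, rotated, cx.graph, symmetry_corrected=True) < 1e-3


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_rmsd_pseudo_metric(butane_complex, seed):
    cx = butane_complex
    rng = np.random.default_rng(seed)
    a, b, c = (cx.crystal + rng.normal(0, 2, cx.crystal.shape) for _ in range(3))
    rab = rmsd(a, b, cx.graph, symmetry_corrected=True)
    rba = rmsd(b, a, cx.graph, symmetry_corrected=True)
    rac = rmsd(a, c, cx.graph, symmetry_corrected=True)
    rcb = rmsd(c, b, cx.graph, symmetry_corrected=True)
    assert np.isclose(rab, rba, atol=1e-10)
    assert rab <= rac + rcb + 1e-10
    assert rmsd(a, a, cx.graph, symmetry_corrected=True) == 0.0
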