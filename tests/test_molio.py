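"""Ligand featurization, pocket extraction/filters, SDF round trips."""

import numpy as np
import pytest

from plantain.errors import EmptyPocketError, MoleculeParseError, MultiMoleculeError
from plantain.molio import (
    PocketDefinition,
    extract_pocket,
    filter_pocket,
    pocket_from_arrays,
    read_ligand,
    write_poses,
)

from conftest import write_receptor_pdb


@pytest.mark.parametrize(
    "smiles,n_heavy,n_bonds,n_rot",
    [
        ("CCO", 3, 2, 0),         # both bonds touch a terminal heavy atom
        ("c1ccccc1", 6, 6, 0),    # all ring bonds
        ("CCCC", 4, 3, 1),        # the central C-C
        ("CCCCC", 5, 4, 2),
        ("CC(=O)NC", 5, 4, 0),    # amide C-N excluded
        ("COCCOC", 6, 5, 3),
    ],
)
def test_rotatable_bond_enumeration(smiles, n_heavy, n_bonds, n_rot):
    graph, coords = read_ligand(smiles, format="smiles")
    assert coords is None
    assert graph.heavy_atom_count == n_heavy
    assert len(graph.bonds) == n_bonds
    assert graph.n_torsions == n_rot
    for b in graph.bonds:
        assert 0 <= b.i < b.j < n_heavy


def test_benzene_features_aromatic():
    graph, _ = read_ligand("c1ccccc1")
    assert all(a.aromatic and a.element == "C" for a in graph.atoms)
    assert all(b.order == "aromatic" for b in graph.bonds)


def test_butane_moving_side_tie_break():
    """Equal halves: the side with the higher-indexed bond endpoint moves."""
    graph, _ = read_ligand("CCCC")
    rb = graph.rotatable_bonds[0]
    assert rb.moving_atoms == (2, 3)
    assert rb.fixed_atom == 1 and rb.moving_atom == 2
    assert len(rb.moving_atoms) <= graph.heavy_atom_count - len(rb.moving_atoms)


def test_rotatable_moving_side_is_component():
    graph, _ = read_ligand("COCCOC")
    for rb in graph.rotatable_bonds:
        moving = set(rb.moving_atoms)
        assert rb.moving_atom in moving and rb.fixed_atom not in moving
        # removal of the bond disconnects moving side from the rest
        for b in graph.bonds:
            if {b.i, b.j} == {rb.fixed_atom, rb.moving_atom}:
                continue
            assert not (b.i in moving) ^ (b.j in moving)


def test_parse_errors():
    with pytest.raises(MoleculeParseError):
        read_ligand("not_a_smiles((", format="smiles")
    with pytest.raises(ValueError):
        read_ligand("CC", format="mol2")


def test_multi_molecule_sdf_rejected(tmp_path, butane_complex):
    path = tmp_path / "two.sdf"
    write_poses(
        butane_complex.graph,
        [butane_complex.crystal, butane_complex.crystal + 1.0],
        [0.0, 1.0],
        path,
    )
    with pytest.raises(MultiMoleculeError):
        read_ligand(str(path), format="sdf")


def test_featurization_deterministic():
    g1, _ = read_ligand("CC(=O)NC")
    g2, _ = read_ligand("CC(=O)NC")
    assert g1 == g2


# -- pocket extraction ------------------------------------------------------

def test_extract_pocket_distance_cutoffs(three_residue_receptor):
    ligand = [np.zeros((1, 3))]
    p5 = extract_pocket(three_residue_receptor, ligand, PocketDefinition(distance_cutoff=5))
    assert p5.n_residues == 1 and p5.residue_classes == ["ALA"]
    p7 = extract_pocket(three_residue_receptor, ligand, PocketDefinition(distance_cutoff=7))
    assert p7.n_residues == 2
    with pytest.raises(EmptyPocketError):
        extract_pocket(three_residue_receptor, ligand, PocketDefinition(distance_cutoff=1))


def test_extract_pocket_union_of_poses(three_residue_receptor):
    near_first = np.zeros((1, 3))
    near_last = np.array([[12.0, 1.0, 0.0]])
    union = extract_pocket(
        three_residue_receptor, [near_first, near_last], PocketDefinition(distance_cutoff=4)
    )
    assert sorted(union.residue_classes) == ["ALA", "SER"]


@pytest.mark.parametrize("c1,c2", [(3.5, 5.0), (5.0, 7.0), (7.0, 13.0)])
def test_pocket_selection_monotone_in_cutoff(three_residue_receptor, c1, c2):
    ligand = [np.zeros((1, 3))]
    small = extract_pocket(three_residue_receptor, ligand, PocketDefinition(distance_cutoff=c1))
    big = extract_pocket(three_residue_receptor, ligand, PocketDefinition(distance_cutoff=c2))
    assert set(small.residue_classes) <= set(big.residue_classes)


def test_extraction_invariant_under_atom_reordering(tmp_path):
    residues = [
        ("ALA", [("CA", "C", (3.0, 0.0, 0.0)), ("C2", "C", (3.5, 1.0, 0.0))]),
        ("GLY", [("CA", "C", (4.0, -1.0, 0.0))]),
    ]
    p1 = write_receptor_pdb(tmp_path / "fwd.pdb", residues)
    p2 = write_receptor_pdb(tmp_path / "rev.pdb", residues[::-1])
    ligand = [np.zeros((1, 3))]
    a = extract_pocket(p1, ligand, PocketDefinition(distance_cutoff=6))
    b = extract_pocket(p2, ligand, PocketDefinition(distance_cutoff=6))
    assert sorted(a.residue_classes) == sorted(b.residue_classes)
    np.testing.assert_allclose(
        np.sort(a.atom_coords, axis=0), np.sort(b.atom_coords, axis=0), atol=1e-3
    )


def test_residue_edges_within_10A(butane_complex):
    pk = butane_complex.pocket
    from scipy.spatial.distance import cdist

    d = cdist(pk.ca_coords, pk.ca_coords)
    expected = {(a, b) for a in range(pk.n_residues) for b in range(a + 1, pk.n_residues)
                if d[a, b] <= 10.0}
    got = {tuple(e) for e in pk.residue_edges}
    assert got == expected


def test_centroid_is_heavy_atom_mean(butane_complex):
    pk = butane_complex.pocket
    np.testing.assert_allclose(pk.centroid, pk.atom_coords.mean(axis=0))


# -- filters ----------------------------------------------------------------

def _simple_pocket(n_residues, span=20.0):
    rng = np.random.default_rng(1)
    coords = rng.uniform(0, span, size=(n_residues, 3))
    return pocket_from_arrays(
        ["ALA"] * n_residues, coords, ["C"] * n_residues,
        ["ALA"] * n_residues, np.arange(n_residues), coords,
    )


def test_filter_too_few_residues():
    verdict = filter_pocket(_simple_pocket(4))
    assert not verdict and "too few residues" in verdict.reason


def test_filter_bounding_box():
    pocket = _simple_pocket(10)
    pocket.atom_coords[0, 0] += 50.0
    verdict = filter_pocket(pocket)
    assert not verdict and "bounding box" in verdict.reason


def test_filter_pass():
    assert filter_pocket(_simple_pocket(10, span=20.0))


def test_pocket_definition_validates():
    with pytest.raises(ValueError):
        PocketDefinition(distance_cutoff=-1.0)


# -- writing ----------------------------------------------------------------

def test_write_poses_round_trip(tmp_path, diglyme_complex):
    path = tmp_path / "pose.sdf"
    write_poses(diglyme_complex.graph, [diglyme_complex.crystal], [0.5], path)
    graph, coords = read_ligand(str(path), format="sdf")
    assert graph == diglyme_complex.graph
    np.testing.assert_allclose(coords, diglyme_complex.crystal, atol=1e-4)
    from rdkit import Chem

    mol = next(iter(Chem.SDMolSupplier(str(path))))
    assert mol.GetDoubleProp("plantain_score") == 0.5


def test_write_poses_errors(tmp_path, butane_complex):
    with pytest.raises(ValueError):
        write_poses(butane_complex.graph, [], [], tmp_path / "x.sdf")
    with pytest.raises(ValueError):
        write_poses(butane_complex.graph, [np.zeros((2, 3))], [0.0], tmp_path / "x.sdf")
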