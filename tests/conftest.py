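"""Shared fixtures: toy complexes and synthetic receptor PDB files."""

import numpy as np
import pytest

from plantain.fixtures import FixtureSpec, make_toy_complex


@pytest.fixture(scope="session")
def butane_complex():
    return make_toy_complex(FixtureSpec("butane", n_residues=8, radius=6.0, seed=20))


@pytest.fixture(scope="session")
def pentane_complex():
    return make_toy_complex(FixtureSpec("pentane", n_residues=8, radius=6.0, seed=21))


@pytest.fixture(scope="session")
def diglyme_complex():
    return make_toy_complex(FixtureSpec("diglyme_core", n_residues=8, radius=6.0, seed=22))


@pytest.fixture(scope="session")
def benzene_complex():
    return make_toy_complex(FixtureSpec("benzene", n_residues=8, radius=6.0, seed=23))


def write_receptor_pdb(path, residues):
    """Write a minimal receptor PDB.

    ``residues`` is a list of (res_name, [(atom_name, element, xyz), ...]).
    """
    import biotite.structure as struc
    from biotite.structure.io import pdb as bpdb

    n = sum(len(atoms) for _, atoms in residues)
    arr = struc.AtomArray(n)
    k = 0
    for ri, (res_name, atoms) in enumerate(residues):
        for name, element, xyz in atoms:
            arr.chain_id[k] = "A"
            arr.res_id[k] = ri + 1
            arr.res_name[k] = res_name
            arr.atom_name[k] = name
            arr.element[k] = element
            arr.hetero[k] = False
            arr.coord[k] = xyz
            k += 1
    f = bpdb.PDBFile()
    bpdb.set_structure(f, arr)
    f.write(str(path))
    return path


@pytest.fixture()
def three_residue_receptor(tmp_path):
    """Three single-CA residues at 3 / 6 / 12 A from the origin."""
    return write_receptor_pdb(
        tmp_path / "three.pdb",
        [
            ("ALA", [("CA", "C", (3.0, 0.0, 0.0))]),
            ("GLY", [("CA", "C", (6.0, 0.0, 0.0))]),
            ("SER", [("CA", "C", (12.0, 0.0, 0.0))]),
        ],
    )
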