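"""Molecular I/O and featurization.

Reads ligands (SMILES / SDF) into a light-weight 2D chemical graph, extracts
binding pockets from receptor PDB files, applies the pocket filters used for
dataset curation, and writes scored poses back to SDF.

Ligands are handled heavy-atom-only: hydrogens are implicit, their counts kept
as an atom feature.  Pockets keep only standard amino-acid residues and their
heavy atoms; the residue-level graph connects residues whose alpha-carbons are
within 10 A.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem  # noqa: F401  (registers SDF/forcefield code)
from scipy.spatial.distance import cdist

from .errors import EmptyPocketError, MoleculeParseError, MultiMoleculeError

__all__ = [
    "AtomFeatures",
    "Bond",
    "RotatableBond",
    "LigandGraph",
    "PocketStructure",
    "PocketDefinition",
    "PocketFilterResult",
    "read_ligand",
    "read_sdf_coords",
    "extract_pocket",
    "pocket_from_arrays",
    "filter_pocket",
    "write_poses",
    "graph_to_mol",
    "STANDARD_AA",
]

HYBRIDIZATIONS = ("sp", "sp2", "sp3", "other")
BOND_ORDERS = ("single", "double", "triple", "aromatic")

STANDARD_AA = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

_RDKIT_HYB = {
    Chem.HybridizationType.SP: "sp",
    Chem.HybridizationType.SP2: "sp2",
    Chem.HybridizationType.SP3: "sp3",
}
_RDKIT_BOND = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}
_BOND_TO_RDKIT = {
    "single": Chem.BondType.SINGLE,
    "double": Chem.BondType.DOUBLE,
    "triple": Chem.BondType.TRIPLE,
    "aromatic": Chem.BondType.AROMATIC,
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomFeatures:
    element: str
    formal_charge: int
    hybridization: str  # one of HYBRIDIZATIONS
    n_hydrogens: int
    aromatic: bool


@dataclass(frozen=True)
class Bond:
    i: int  # lower atom index
    j: int  # higher atom index
    order: str  # one of BOND_ORDERS


@dataclass(frozen=True)
class RotatableBond:
    bond_index: int
    fixed_atom: int   # bond endpoint on the static side
    moving_atom: int  # bond endpoint on the moving side
    moving_atoms: tuple[int, ...]  # sorted atom indices of the moving side


@dataclass(frozen=True)
class LigandGraph:
    """2D heavy-atom chemical graph with rotatable-bond bookkeeping."""

    atoms: tuple[AtomFeatures, ...]
    bonds: tuple[Bond, ...]
    rotatable_bonds: tuple[RotatableBond, ...]

    @property
    def heavy_atom_count(self) -> int:
        return len(self.atoms)

    @property
    def n_torsions(self) -> int:
        return len(self.rotatable_bonds)


@dataclass
class PocketStructure:
    """Residue-level graph plus atomic-level heavy atoms of a binding site."""

    residue_classes: list[str]          # 3-letter amino-acid codes
    ca_coords: np.ndarray               # (R, 3) alpha-carbon coordinates, A
    residue_edges: np.ndarray           # (E, 2) int residue-index pairs
    residue_edge_distances: np.ndarray  # (E,) alpha-carbon distances, A
    atom_elements: list[str]
    atom_residue_classes: list[str]
    atom_residue_index: np.ndarray      # (P,) parent residue index
    atom_coords: np.ndarray             # (P, 3) heavy-atom coordinates, A

    RESIDUE_EDGE_CUTOFF = 10.0  # A, closed comparison

    @property
    def n_residues(self) -> int:
        return len(self.residue_classes)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_elements)

    @property
    def centroid(self) -> np.ndarray:
        """Unweighted mean of all pocket heavy-atom coordinates."""
        return self.atom_coords.mean(axis=0)

    @classmethod
    def build(
        cls,
        residue_classes,
        ca_coords,
        atom_elements,
        atom_residue_classes,
        atom_residue_index,
        atom_coords,
    ) -> "PocketStructure":
        ca_coords = np.asarray(ca_coords, dtype=float).reshape(-1, 3)
        atom_coords = np.asarray(atom_coords, dtype=float).reshape(-1, 3)
        n = len(residue_classes)
        pairs, dists = [], []
        if n > 1:
            d = cdist(ca_coords, ca_coords)
            for a in range(n):
                for b in range(a + 1, n):
                    if d[a, b] <= cls.RESIDUE_EDGE_CUTOFF:
                        pairs.append((a, b))
                        dists.append(d[a, b])
        return cls(
            residue_classes=list(residue_classes),
            ca_coords=ca_coords,
            residue_edges=np.asarray(pairs, dtype=int).reshape(-1, 2),
            residue_edge_distances=np.asarray(dists, dtype=float),
            atom_elements=list(atom_elements),
            atom_residue_classes=list(atom_residue_classes),
            atom_residue_index=np.asarray(atom_residue_index, dtype=int),
            atom_coords=atom_coords,
        )


@dataclass(frozen=True)
class PocketDefinition:
    """Residue-selection rule and curation filters for binding pockets."""

    distance_cutoff: float = 5.0   # A, atom-atom distance to any reference ligand
    min_residues: int = 5
    max_box_side: float = 42.0     # A, axis-aligned bounding box of pocket atoms

    def __post_init__(self):
        if self.distance_cutoff <= 0 or self.max_box_side <= 0:
            raise ValueError("pocket cutoffs must be strictly positive")


@dataclass(frozen=True)
class PocketFilterResult:
    passed: bool
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.passed


# ---------------------------------------------------------------------------
# ligand reading / featurization
# ---------------------------------------------------------------------------

def _mol_to_graph(mol: Chem.Mol) -> LigandGraph:
    if mol.GetNumHeavyAtoms() < 1:
        raise MoleculeParseError("molecule has no heavy atoms")
    mol = Chem.RemoveHs(mol)
    atoms = []
    for atom in mol.GetAtoms():
        atoms.append(
            AtomFeatures(
                element=atom.GetSymbol(),
                formal_charge=atom.GetFormalCharge(),
                hybridization=_RDKIT_HYB.get(atom.GetHybridization(), "other"),
                n_hydrogens=atom.GetTotalNumHs(),
                aromatic=atom.GetIsAromatic(),
            )
        )
    bonds = []
    for bond in mol.GetBonds():
        order = _RDKIT_BOND.get(bond.GetBondType())
        if order is None:
            raise MoleculeParseError(
                f"unsupported bond type {bond.GetBondType()} between atoms "
                f"{bond.GetBeginAtomIdx()}-{bond.GetEndAtomIdx()}"
            )
        i, j = sorted((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
        bonds.append(Bond(i=i, j=j, order=order))
    rotatable = _enumerate_rotatable_bonds(mol, bonds)
    return LigandGraph(atoms=tuple(atoms), bonds=tuple(bonds), rotatable_bonds=rotatable)


def _is_amide_bond(mol: Chem.Mol, i: int, j: int) -> bool:
    """C-N single bond where the carbon also carries a double bond to oxygen."""
    for c_idx, n_idx in ((i, j), (j, i)):
        c, n = mol.GetAtomWithIdx(c_idx), mol.GetAtomWithIdx(n_idx)
        if c.GetSymbol() != "C" or n.GetSymbol() != "N":
            continue
        for nb_bond in c.GetBonds():
            other = nb_bond.GetOtherAtom(c)
            if other.GetSymbol() == "O" and nb_bond.GetBondType() == Chem.BondType.DOUBLE:
                return True
    return False


def _components_without_bond(n_atoms: int, bonds, skip: int) -> list[set[int]]:
    adj: dict[int, list[int]] = {i: [] for i in range(n_atoms)}
    for bi, b in enumerate(bonds):
        if bi == skip:
            continue
        adj[b.i].append(b.j)
        adj[b.j].append(b.i)
    seen: set[int] = set()
    comps = []
    for start in range(n_atoms):
        if start in seen:
            continue
        comp = {start}
        queue = [start]
        while queue:
            cur = queue.pop()
            for nb in adj[cur]:
                if nb not in comp:
                    comp.add(nb)
                    queue.append(nb)
        seen |= comp
        comps.append(comp)
    return comps


def _enumerate_rotatable_bonds(mol: Chem.Mol, bonds: list[Bond]) -> tuple[RotatableBond, ...]:
    """Non-ring single bonds with both endpoints having >= 2 heavy neighbors,
    excluding amide C-N bonds.  The moving side is the smaller fragment; ties
    go to the side containing the bond's higher-indexed endpoint."""
    out = []
    for bi, b in enumerate(bonds):
        rd_bond = mol.GetBondBetweenAtoms(b.i, b.j)
        if rd_bond.IsInRing() or rd_bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        deg_i = mol.GetAtomWithIdx(b.i).GetDegree()
        deg_j = mol.GetAtomWithIdx(b.j).GetDegree()
        if deg_i < 2 or deg_j < 2:
            continue  # terminal heavy atom on one side
        if _is_amide_bond(mol, b.i, b.j):
            continue
        comps = _components_without_bond(mol.GetNumAtoms(), bonds, bi)
        if len(comps) != 2:
            continue  # bond is in a cycle not flagged as ring (defensive)
        side_i = next(c for c in comps if b.i in c)
        side_j = next(c for c in comps if b.j in c)
        if len(side_i) < len(side_j):
            moving, fixed_atom, moving_atom = side_i, b.j, b.i
        elif len(side_j) < len(side_i):
            moving, fixed_atom, moving_atom = side_j, b.i, b.j
        else:  # tie: the side containing the higher-indexed endpoint moves
            moving, fixed_atom, moving_atom = side_j, b.i, b.j
        out.append(
            RotatableBond(
                bond_index=bi,
                fixed_atom=fixed_atom,
                moving_atom=moving_atom,
                moving_atoms=tuple(sorted(moving)),
            )
        )
    return tuple(out)


def read_ligand(path_or_smiles: str, format: str = "smiles"):
    """Read a single ligand.

    Returns ``(LigandGraph, coords-or-None)``; coordinates (heavy atoms, A)
    are returned when the SDF record carries a 3D conformer.
    """
    if format == "smiles":
        mol = Chem.MolFromSmiles(str(path_or_smiles))
        if mol is None:
            raise MoleculeParseError(f"could not parse SMILES {path_or_smiles!r}")
        return _mol_to_graph(mol), None
    if format == "sdf":
        supplier = Chem.SDMolSupplier(str(path_or_smiles), removeHs=True)
        mols = [m for m in supplier]
        if any(m is None for m in mols):
            raise MoleculeParseError(
                f"unparseable record in SDF {path_or_smiles!r}"
            )
        if len(mols) == 0:
            raise MoleculeParseError(f"no molecules in SDF {path_or_smiles!r}")
        if len(mols) > 1:
            raise MultiMoleculeError(
                f"SDF {path_or_smiles!r} holds {len(mols)} molecules; "
                "use read_sdf_coords for multi-record files"
            )
        mol = mols[0]
        graph = _mol_to_graph(mol)
        coords = None
        if mol.GetNumConformers() > 0:
            coords = np.array(mol.GetConformer().GetPositions(), dtype=float)
        return graph, coords
    raise ValueError(f"unknown ligand format {format!r}")


def read_sdf_coords(path) -> list[np.ndarray]:
    """Heavy-atom coordinate arrays for every record of a (multi-)SDF."""
    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    out = []
    for k, mol in enumerate(supplier):
        if mol is None:
            raise MoleculeParseError(f"unparseable record {k} in SDF {path!r}")
        if mol.GetNumConformers() == 0:
            raise MoleculeParseError(f"record {k} in SDF {path!r} has no 3D coordinates")
        out.append(np.array(mol.GetConformer().GetPositions(), dtype=float))
    if not out:
        raise MoleculeParseError(f"no molecules in SDF {path!r}")
    return out


# ---------------------------------------------------------------------------
# pocket extraction & filters
# ---------------------------------------------------------------------------

def _receptor_residues(receptor_pdb):
    """Standard-amino-acid residues (heavy atoms only) from a PDB file."""
    import biotite.structure as struc
    from biotite.structure.io import pdb as bpdb

    pdb_file = bpdb.PDBFile.read(str(receptor_pdb))
    arr = bpdb.get_structure(pdb_file, model=1)
    keep = np.isin(arr.res_name, STANDARD_AA) & (arr.element != "H")
    arr = arr[keep]
    residues = []
    starts = struc.get_residue_starts(arr, add_exclusive_stop=True)
    for s, e in zip(starts[:-1], starts[1:]):
        seg = arr[s:e]
        ca = seg[seg.atom_name == "CA"]
        if len(ca) == 0:
            continue  # residue without an alpha-carbon record is unusable
        residues.append(
            {
                "res_name": str(seg.res_name[0]),
                "ca": np.asarray(ca.coord[0], dtype=float),
                "elements": [str(el) for el in seg.element],
                "coords": np.asarray(seg.coord, dtype=float),
            }
        )
    return residues


def extract_pocket(receptor_pdb, ligand_poses, definition: PocketDefinition | None = None) -> PocketStructure:
    """Pocket = all residues with any heavy atom within the cutoff of any
    heavy atom of any provided reference ligand pose."""
    definition = definition or PocketDefinition()
    poses = [np.asarray(p, dtype=float).reshape(-1, 3) for p in ligand_poses]
    if not poses:
        raise ValueError("at least one reference ligand pose is required")
    lig = np.concatenate(poses, axis=0)
    residues = _receptor_residues(receptor_pdb)
    selected = [
        r for r in residues
        if cdist(r["coords"], lig).min() <= definition.distance_cutoff
    ]
    if not selected:
        raise EmptyPocketError(
            f"no residue within {definition.distance_cutoff} A of the reference ligands"
        )
    return _pocket_from_residues(selected)


def _pocket_from_residues(selected) -> PocketStructure:
    atom_elements, atom_classes, atom_res_idx, atom_coords = [], [], [], []
    for ri, r in enumerate(selected):
        for el, xyz in zip(r["elements"], r["coords"]):
            atom_elements.append(el)
            atom_classes.append(r["res_name"])
            atom_res_idx.append(ri)
            atom_coords.append(xyz)
    return PocketStructure.build(
        residue_classes=[r["res_name"] for r in selected],
        ca_coords=np.array([r["ca"] for r in selected]),
        atom_elements=atom_elements,
        atom_residue_classes=atom_classes,
        atom_residue_index=atom_res_idx,
        atom_coords=np.array(atom_coords),
    )


def pocket_from_arrays(residue_classes, ca_coords, atom_elements,
                       atom_residue_classes, atom_residue_index, atom_coords) -> PocketStructure:
    """Assemble a pocket directly from arrays (synthetic fixtures)."""
    return PocketStructure.build(
        residue_classes, ca_coords, atom_elements,
        atom_residue_classes, atom_residue_index, atom_coords,
    )


def filter_pocket(pocket: PocketStructure, definition: PocketDefinition | None = None) -> PocketFilterResult:
    definition = definition or PocketDefinition()
    if pocket.n_residues < definition.min_residues:
        return PocketFilterResult(
            False,
            f"too few residues ({pocket.n_residues} < {definition.min_residues})",
        )
    extent = pocket.atom_coords.max(axis=0) - pocket.atom_coords.min(axis=0)
    if np.any(extent > definition.max_box_side):
        side = float(extent.max())
        return PocketFilterResult(
            False,
            f"bounding box side {side:.1f} A exceeds {definition.max_box_side} A",
        )
    return PocketFilterResult(True, None)


# ---------------------------------------------------------------------------
# writing poses
# ---------------------------------------------------------------------------

def graph_to_mol(graph: LigandGraph) -> Chem.Mol:
    """Rebuild an RDKit molecule (heavy atoms only) from a LigandGraph."""
    rw = Chem.RWMol()
    for a in graph.atoms:
        atom = Chem.Atom(a.element)
        atom.SetFormalCharge(a.formal_charge)
        atom.SetNumExplicitHs(a.n_hydrogens)
        atom.SetNoImplicit(True)
        atom.SetIsAromatic(a.aromatic)
        rw.AddAtom(atom)
    for b in graph.bonds:
        rw.AddBond(b.i, b.j, _BOND_TO_RDKIT[b.order])
        if b.order == "aromatic":
            rw.GetBondBetweenAtoms(b.i, b.j).SetIsAromatic(True)
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        Chem.SanitizeMol(
            mol,
            Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE,
        )
    return mol


SCORE_FIELD = "plantain_score"


def write_poses(graph: LigandGraph, poses, scores, path) -> None:
    """One SDF record per pose, score stored in the ``plantain_score`` field."""
    poses = [np.asarray(p, dtype=float) for p in poses]
    if len(poses) == 0:
        raise ValueError("no poses to write")
    if len(scores) != len(poses):
        raise ValueError("scores and poses must have equal length")
    for p in poses:
        if p.shape != (graph.heavy_atom_count, 3):
            raise ValueError(
                f"pose shape {p.shape} does not match heavy-atom count "
                f"{graph.heavy_atom_count}"
            )
    mol = graph_to_mol(graph)
    writer = Chem.SDWriter(str(path))
    try:
        for pose, score in zip(poses, scores):
            conf = Chem.Conformer(mol.GetNumAtoms())
            for i, xyz in enumerate(pose):
                conf.SetAtomPosition(i, tuple(float(v) for v in xyz))
            m = Chem.Mol(mol)
            m.RemoveAllConformers()
            m.AddConformer(conf, assignId=True)
            m.SetDoubleProp(SCORE_FIELD, float(score))
            writer.write(m)
    finally:
        writer.close()
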