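"""Exception types shared across the package."""


class PlantainError(Exception):
    """Base class for all package-specific errors."""


class MoleculeParseError(PlantainError):
    """A SMILES string or SDF record could not be parsed."""


class MultiMoleculeError(MoleculeParseError):
    """A single-molecule reader was handed a multi-record SDF."""


class EmptyPocketError(PlantainError):
    """No receptor residue lies within the cutoff of any reference ligand."""


class UnknownFeatureError(PlantainError):
    """An atom/bond/residue feature falls outside the closed vocabulary."""


class DockingError(PlantainError):
    """Conformer embedding failed or every docking restart diverged."""


class TrainingDivergedError(PlantainError):
    """The training loss became non-finite."""
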