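"""Exception hierarchy for cryptohot."""


class CryptoHotError(Exception):
    """Base class for all cryptohot errors."""


class StructureFormatError(CryptoHotError):
    """A coordinate file could not be parsed."""


class EmptyStructureError(CryptoHotError):
    """A structure or model contained no atoms after filtering."""


class CorrespondenceError(CryptoHotError):
    """Too few matched atom pairs for a rigid-body superposition."""


class LigandNotFoundError(CryptoHotError):
    """The requested ligand residue name is absent from the structure."""


class InvalidLigandError(CryptoHotError):
    """A ligand pose without heavy atoms cannot be used for clash detection."""


class TrajectoryError(CryptoHotError):
    """Inconsistent frames inside a trajectory bundle."""


class LatticeMismatchError(CryptoHotError):
    """Voxel objects defined on different lattices were combined."""


class GridFormatError(CryptoHotError):
    """A grid file (OpenDX) could not be parsed."""
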