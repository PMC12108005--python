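"""Exception hierarchy for paleopca."""


class PaleopcaError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PaleopcaError):
    """Malformed EIGENSTRAT input (bad alphabet, ragged rows, ...)."""


class ConsistencyError(PaleopcaError):
    """geno/snp/ind triplet (or panel fields) disagree in shape or content."""


class DegeneratePanelError(PaleopcaError):
    """No usable loci remain after filtering."""


class InsufficientDataError(PaleopcaError):
    """Too few observed loci to estimate the requested number of scores."""


class ConditioningError(PaleopcaError):
    """Gram matrix of the observed eigenvector rows is numerically singular."""


class ValidationError(PaleopcaError):
    """An object violates one of its declared invariants."""
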