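"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` subclasses to 3.
"""


class VacuformError(Exception):
    """Base class for all package errors."""


class ConfigError(VacuformError):
    """Invalid or inconsistent configuration."""


class DataError(VacuformError):
    """Invalid or inconsistent input data."""


class PdbParseError(DataError):
    """Unparseable record in a PDB/XYZ file; message names the line."""


class EmptyStructureError(DataError):
    """A structure file yielded zero atoms."""


class FrameMismatchError(DataError):
    """A trajectory model does not match its topology; message names the model."""


class EmptySelectionError(DataError):
    """An atom selection matched nothing."""


class DegenerateFitError(DataError):
    """Superposition attempted on <3 atoms or a collinear point set."""


class InsufficientSitesError(DataError):
    """Protonation candidates exhausted before the target charge was reached."""

    def __init__(self, message: str, shortfall: int):
        super().__init__(message)
        self.shortfall = shortfall


class ParityError(ConfigError):
    """Symmetric protonation cannot split the charge deficit evenly over chains."""


class DoubleProtonationError(DataError):
    """A protonation plan site is already in its protonated state."""


class UndefinedRatioError(DataError):
    """A recovery fraction has an empty denominator set."""
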