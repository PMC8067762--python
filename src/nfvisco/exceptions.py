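"""Exception hierarchy for the nfvisco pipeline.

Every stage raises a subclass of :class:`NFViscoError` so pipeline drivers
can abort with the failing stage name while preserving partial outputs.
"""


class NFViscoError(Exception):
    """Base class for all nfvisco errors."""


class ParameterError(NFViscoError, ValueError):
    """An argument or generator/config parameter violates its invariants."""


class FormatError(NFViscoError, ValueError):
    """A trajectory or table file does not match the expected dialect."""


class DegeneracyError(NFViscoError, ValueError):
    """Geometric degeneracy (e.g. coincident atoms) prevents tessellation."""


class ConsistencyError(NFViscoError, ValueError):
    """Frames or series disagree (missing atoms, mismatched grids)."""


class AlignmentError(NFViscoError, ValueError):
    """Stress and strain series cannot be placed on a common time grid."""


class InsufficientDataError(NFViscoError, ValueError):
    """Too few samples for the requested estimate."""


class FitFailureError(NFViscoError, RuntimeError):
    """All fit restarts failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class SingularityError(NFViscoError, ValueError):
    """A conversion is singular (e.g. bulk modulus as Poisson's ratio -> 0.5)."""
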