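"""Exception hierarchy for cryact.

All package-specific failures derive from :class:`CryactError` so callers can
catch one base class at pipeline boundaries.
"""


class CryactError(Exception):
    """Base class for all cryact errors."""


class TopologyError(CryactError):
    """Topology file violates the bead-model contract (missing BB, duplicate FLA...)."""


class ParseError(CryactError):
    """A file could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class ShapeError(CryactError):
    """Array/bead-count mismatch between inputs."""


class SelectionError(CryactError):
    """A residue/bead selection is unknown or empty."""


class PBCJumpError(CryactError):
    """Consecutive-frame displacement exceeds the unwrapped-trajectory sanity bound."""


class SpecValidationError(CryactError):
    """A synthetic-data specification violates its invariants."""


class DegeneracyError(CryactError):
    """Superposition fit set is collinear or coincident."""


class FitError(CryactError):
    """Curve fit did not converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class EstimationError(CryactError):
    """Too few frames (or otherwise invalid data) for density estimation."""


class GridError(CryactError):
    """Histogram grids of two distributions do not match."""


class AlignmentError(CryactError):
    """Ensembles were not superposed to a common reference before comparison."""


class NoEventsError(CryactError):
    """Lifetime estimation attempted with zero observed events.

    Carries the censoring-based lower bound on the mean lifetime.
    """

    def __init__(self, message: str, lower_bound: float | None = None):
        super().__init__(message)
        self.lower_bound = lower_bound


class ConfigError(CryactError):
    """Pipeline configuration is invalid or incomplete."""


class StageError(CryactError):
    """A pipeline stage failed; tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
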