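"""Exception hierarchy for petkin."""


class PetkinError(Exception):
    """Base class for all petkin errors."""


class ScheduleError(PetkinError, ValueError):
    """Invalid frame schedule (empty, non-positive durations, overlap, ...)."""


class UnitError(PetkinError, ValueError):
    """Operation applied to a TAC in the wrong unit."""


class TacParseError(PetkinError, ValueError):
    """A TAC table could not be parsed; carries the offending row if known."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class ExtrapolationError(PetkinError, ValueError):
    """Requested schedule extends beyond the support of the blood curve."""


class FitError(PetkinError, RuntimeError):
    """All optimization starts failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        self.diagnostics = diagnostics or []
        super().__init__(message)


class CalibrationError(PetkinError, ValueError):
    """Input-function targets (peak / late mean) are mutually infeasible."""


class InsufficientDataError(PetkinError, ValueError):
    """Not enough usable points (e.g. Logan segment shorter than 3 points)."""
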