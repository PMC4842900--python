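"""Exception hierarchy for popscan."""


class PopscanError(Exception):
    """Base class for all popscan errors."""


class ParameterError(PopscanError, ValueError):
    """A parameter is outside its legal range."""


class GenePlacementError(PopscanError):
    """Non-overlapping gene placement is infeasible ("cannot place genes")."""


class NoRecruitmentError(PopscanError):
    """An operation that requires recruited matches saw none.

    Raised instead of silently returning 0.0 so that "no signal" is never
    confused with "signal of zero".
    """


class FitError(PopscanError):
    """Degenerate input to a distribution fit (too few or constant values)."""


class GateError(PopscanError):
    """A population failed the detection gates required for downstream tests."""

    def __init__(self, gate: str, message: str | None = None):
        self.gate = gate
        super().__init__(message or f"population did not pass the {gate}")


class TableFormatError(PopscanError):
    """Malformed tabular alignment input; carries the offending line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class PipelineStageError(PopscanError):
    """A pipeline stage failed; names the stage and the underlying cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
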