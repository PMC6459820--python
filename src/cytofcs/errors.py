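"""Package-wide exception types."""

from __future__ import annotations


class CytoFCSError(Exception):
    """Base class for package errors."""


class FitConvergenceError(CytoFCSError, RuntimeError):
    """A nonlinear fit failed to converge; carries diagnostics, never silent."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class CalibrationError(CytoFCSError, RuntimeError):
    """Focal-volume calibration rejected (poor single-component fit)."""


class ParseError(CytoFCSError, ValueError):
    """Malformed input file; names the offending line."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = f"{path}:{line}: " if line is not None else (f"{path}: " if path else "")
        super().__init__(f"{loc}{message}")
        self.path = path
        self.line = line


class PipelineStageError(CytoFCSError, RuntimeError):
    """A pipeline stage failed; tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
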