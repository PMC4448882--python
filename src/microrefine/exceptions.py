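"""Exception hierarchy shared across the package."""


class MicrorefineError(Exception):
    """Base class for all package errors."""


class InvalidCellError(MicrorefineError):
    """Unit cell is degenerate (non-positive volume or out-of-range angles)."""


class UndefinedReflectionError(MicrorefineError):
    """An operation was asked about the (0,0,0) 'reflection'."""


class MissingScattererError(MicrorefineError):
    """No scattering-factor coefficients are available for an element."""


class ConstraintConflictError(MicrorefineError):
    """Mutually incompatible parameter constraints (e.g. fixed and shared-free)."""


class RestraintParseError(MicrorefineError):
    """Restraint instruction file could not be parsed.

    Carries the 1-based line number of the offending line.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class FileFormatError(MicrorefineError):
    """Malformed record in a reflection/model/solvent file (names a line)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SingularMatrixError(MicrorefineError):
    """LDL^t met a (numerically) zero pivot; names the implicated parameters."""

    def __init__(self, message: str, parameter_indices=(), parameter_names=()):
        self.parameter_indices = tuple(parameter_indices)
        self.parameter_names = tuple(parameter_names)
        super().__init__(message)


class DivergenceError(MicrorefineError):
    """Refinement objective rose for several consecutive cycles."""

    def __init__(self, message: str, history=None):
        self.history = history or []
        super().__init__(message)


class NothingToRefineError(MicrorefineError):
    """No free parameters, or an all-zero normal-matrix diagonal."""
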