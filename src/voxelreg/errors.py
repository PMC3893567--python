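"""Exception hierarchy shared across the package."""


class VoxelregError(Exception):
    """Base class for all package-specific errors."""


class ContractError(VoxelregError, ValueError):
    """A caller violated an operation's precondition (shape/length mismatch etc.)."""


class FormatError(VoxelregError, ValueError):
    """Unrecognized or unsupported file format."""


class CorruptFileError(VoxelregError, ValueError):
    """A file was recognized but its contents are inconsistent."""


class DegenerateInputError(VoxelregError, ValueError):
    """Input too small or empty for the requested operation."""


class DegenerateOverlapError(VoxelregError, RuntimeError):
    """Too few samples mapped inside the moving image domain."""


class UnsupportedOperationError(VoxelregError, TypeError):
    """The operation is not defined for this kind (e.g. nearest-neighbor gradient)."""


class NumericalError(VoxelregError, RuntimeError):
    """Non-finite values encountered during optimization."""

    def __init__(self, message, iteration=None):
        super().__init__(message)
        self.iteration = iteration


class NonConvergenceError(VoxelregError, RuntimeError):
    """Fixed-point inversion did not reach the requested residual tolerance."""

    def __init__(self, message, residual=None, location=None):
        super().__init__(message)
        self.residual = residual
        self.location = location
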