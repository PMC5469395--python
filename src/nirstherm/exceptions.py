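"""Exception hierarchy shared across the package."""


class NirsthermError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NirsthermError, ValueError):
    """A file or table does not have the required columns/layout."""


class RangeError(NirsthermError, ValueError):
    """A requested value lies outside the supported span (no extrapolation)."""


class DomainError(NirsthermError, ValueError):
    """A physical quantity lies outside its validity domain (e.g. temperature)."""


class DegenerateInputError(NirsthermError, ValueError):
    """Input carries no usable variation (constant channel, zero variance)."""


class CollinearityError(NirsthermError, ValueError):
    """A design/extinction matrix is rank deficient."""


class SelectionError(NirsthermError, ValueError):
    """A wavelength selection cannot be satisfied on the given grid."""


class CompatibilityError(NirsthermError, ValueError):
    """Two objects (model vs recording) do not share a compatible grid."""


class PipelineStageError(NirsthermError, RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str, input_path=None):
        self.stage = stage
        self.input_path = input_path
        loc = f" (input: {input_path})" if input_path is not None else ""
        super().__init__(f"stage '{stage}' failed{loc}: {message}")
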