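"""Exception hierarchy shared across the package."""


class NucleoscatterError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(NucleoscatterError, ValueError):
    """A scalar parameter or configuration field is out of its legal range."""


class ContainmentError(ParameterError):
    """The voxel grid is too small to contain the nuclear body."""


class ResolutionError(ParameterError):
    """The voxel grid cannot resolve the requested physics (Nyquist violation)."""


class DataError(NucleoscatterError, ValueError):
    """Array content violates a contract (non-finite, negative, ...)."""


class FormatError(NucleoscatterError, ValueError):
    """An on-disk artifact does not conform to the expected layout."""


class DegenerateSignalError(DataError):
    """A signal is constant or all-zero and cannot be processed."""


class DivergenceError(NucleoscatterError, RuntimeError):
    """Training produced a non-finite loss."""


class ConfigError(NucleoscatterError, ValueError):
    """An experiment configuration failed validation."""
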