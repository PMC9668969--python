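"""Shared exception types."""


class LipidFluxError(Exception):
    """Base class for all package errors."""


class ParameterError(LipidFluxError, ValueError):
    """An input parameter violates its documented constraints."""


class FitError(LipidFluxError, RuntimeError):
    """A fit could not be performed on the given data."""


class DataError(LipidFluxError, ValueError):
    """A data file or in-memory dataset violates its contract."""
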