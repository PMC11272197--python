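"""Exception hierarchy for adiposeg.

All package errors derive from :class:`AdiposegError` so callers can catch
one base class; user-input problems additionally derive from ``ValueError``.
"""


class AdiposegError(Exception):
    """Base class for all adiposeg errors."""


class ConfigurationError(AdiposegError, ValueError):
    """A spec/config object violates its invariants; message names the field."""


class FormatError(AdiposegError, ValueError):
    """An on-disk image or table does not carry the metadata we require."""


class DomainError(AdiposegError, ValueError):
    """A numeric input is outside the mathematical domain of an operation."""


class UnitError(AdiposegError, ValueError):
    """A measurement carries an unknown or unsupported unit."""


class DegenerateInputError(AdiposegError, ValueError):
    """Input with zero dynamic range / zero variance where variation is required."""


class EmptySliceError(AdiposegError, ValueError):
    """A slice contains no above-threshold tissue at all."""


class CollinearityError(AdiposegError, ValueError):
    """Covariate matrix is singular; partial correlation is undefined."""


class EditError(AdiposegError, ValueError):
    """An edit-script entry is invalid; message carries the edit index."""
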