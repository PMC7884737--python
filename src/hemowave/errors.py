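"""Exception hierarchy.

Every error raised by this package derives from :class:`HemowaveError`,
so callers (and the CLI) can distinguish user/data problems from bugs.
"""


class HemowaveError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HemowaveError):
    """A configuration value is invalid; the message names the field."""


class SchemaError(HemowaveError):
    """A required channel or column is missing from an input file."""


class FormatError(HemowaveError):
    """An input file is malformed (bad delimiter, non-uniform time axis...)."""


class PolicyError(HemowaveError):
    """Input violates a data-quality policy (e.g. non-finite samples)."""


class UnitError(HemowaveError):
    """Unsupported unit or unit pair in a conversion."""


class SegmentationError(HemowaveError):
    """R-peak detection failed (flat signal, fewer than two beats...)."""


class InsufficientDataError(HemowaveError):
    """Fewer beats available than requested for ensemble averaging."""


class LandmarkError(HemowaveError):
    """Ejection landmarks could not be located."""


class ImpedanceError(HemowaveError):
    """Input impedance undefined (e.g. zero mean flow)."""


class BandError(HemowaveError):
    """No usable harmonic inside the requested frequency band."""


class ParameterError(HemowaveError):
    """A scalar parameter is out of its physical range."""


class StatisticsError(HemowaveError):
    """A statistical test is undefined for the given data."""


class PairingError(HemowaveError):
    """Paired comparison input is incomplete (missing subject/condition)."""
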