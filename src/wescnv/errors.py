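"""Exception hierarchy for wescnv.

Every error raised on purpose by this package derives from :class:`WescnvError`,
so callers (and the CLI) can catch one base class.
"""


class WescnvError(Exception):
    """Base class for all wescnv errors."""


class ParseError(WescnvError):
    """A line of an input file could not be parsed; the message names the line."""


class ValidationError(WescnvError):
    """Parsed input violates a domain invariant (coordinates, GC range, overlap...)."""


class AlignmentError(WescnvError):
    """Per-target data does not line up with the shared target grid."""


class FormatError(WescnvError):
    """A file or archive does not have the expected overall structure."""


class AssignmentError(WescnvError):
    """A sample could not be assigned a patient/control role."""


class DegenerateSampleError(WescnvError):
    """A sample carries no usable signal (e.g. all-zero counts)."""


class EmptyProfileError(WescnvError):
    """An observation profile has no unmasked targets left."""


class ParameterError(WescnvError):
    """A tuning parameter is outside its legal range."""


class InputError(WescnvError):
    """Inconsistent inputs to an analysis operation (e.g. unknown sample id)."""


class NumericalError(WescnvError):
    """A numerical routine produced a non-finite quantity."""


class ConfigError(WescnvError):
    """A configuration is internally infeasible."""
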