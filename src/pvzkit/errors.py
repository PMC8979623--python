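"""Exception hierarchy.

Every failure mode the pipeline can report derives from :class:`PvzError`
so that callers (and the CLI) can catch one type and still present the
specific category in the message.
"""


class PvzError(Exception):
    """Base class for all pvzkit errors."""


class InputError(PvzError):
    """Unreadable, malformed or physically impossible input."""


class ConfigError(PvzError):
    """Invalid session/region/calibration configuration."""


class DetectionError(PvzError):
    """A trace, envelope or R peak could not be found."""


class DataError(PvzError):
    """Signal content violates an operation's assumptions."""


class UnitError(PvzError):
    """Physical-unit mismatch or unknown target unit."""


class SelectionError(PvzError):
    """Invalid beat include/exclude request."""


class RangeError(PvzError):
    """Requested harmonic index beyond the computed spectrum."""


class DegenerateFlowError(DataError):
    """A flow harmonic is numerically zero, so the impedance ratio is undefined."""


class RenderError(PvzError):
    """Synthetic capture cannot be rendered with the given style."""
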