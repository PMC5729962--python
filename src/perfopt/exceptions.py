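"""Exception hierarchy for perfopt.

All package-specific failures derive from :class:`PerfoptError` so callers can
catch one base class at pipeline level while per-scan handling distinguishes
recoverable analysis failures (flat curves, failed crossings) from hard input
errors (bad formats, nonphysical parameters).
"""


class PerfoptError(Exception):
    """Base class for all perfopt errors."""


class FormatError(PerfoptError):
    """Unreadable or malformed on-disk data (bad magic, unsorted ticks...)."""


class FlatCurveError(PerfoptError):
    """No plateau pair on an autocorrelation curve passes the contrast guard.

    Raised for curves with no measurable decay; pipeline code treats the scan
    as 'no decay detected' rather than aborting a series.
    """


class NoCrossingError(PerfoptError):
    """A g2 curve never reaches the half-decay target between its plateaus."""


class CalibrationError(PerfoptError):
    """Spectral calibration failed (non-positive reference, degenerate model)."""


class LUTRangeError(PerfoptError):
    """A lookup-table query falls outside the grid's convex hull."""

    def __init__(self, message: str, axis: str | None = None):
        super().__init__(message)
        self.axis = axis
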