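"""Exception hierarchy for sigrow.

All errors raised by the library derive from :class:`SigrowError`, so callers
(and the CLI) can catch one base class.  Parameter/domain problems are also
``ValueError`` subclasses, input-data problems are also ``ValueError``, and
file problems carry enough context (path, row) to be actionable.
"""


class SigrowError(Exception):
    """Base class for all sigrow errors."""


class ParameterError(SigrowError, ValueError):
    """Invalid model parameters (violated invariants such as k <= 0)."""


class DomainError(SigrowError, ValueError):
    """Model evaluated outside its mathematical domain (e.g. BSG at t < t_b)."""


class SeriesError(SigrowError, ValueError):
    """Invalid growth series (unordered times, negative biomass, ...)."""


class FitError(SigrowError, RuntimeError):
    """Fitting cannot proceed on this input."""


class TooFewPointsError(FitError):
    """Fewer observations than required to identify the four parameters."""


class DegenerateSeriesError(FitError):
    """Series with zero biomass variance; SST = 0 and R^2 is undefined."""


class FileFormatError(SigrowError, ValueError):
    """A series file could not be parsed; message names the file and row."""


class UnknownSpeciesError(SigrowError, KeyError):
    """Requested crop fixture is not one of the eight bundled species."""
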