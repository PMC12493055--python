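"""Exception hierarchy shared by all analysis arms."""


class GxeError(Exception):
    """Base class for all gxekit errors."""


class ParameterError(GxeError, ValueError):
    """A configuration value or argument is outside its documented domain."""


class InsufficientDataError(GxeError):
    """Too few usable records/instruments/events to run the requested analysis."""


class ConvergenceError(GxeError):
    """An iterative fit failed to converge; the message carries the trace."""
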