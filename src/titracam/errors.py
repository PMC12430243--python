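"""Exception hierarchy shared across the pipeline."""


class TitracamError(Exception):
    """Base class for all pipeline errors."""


class NoSignalError(TitracamError):
    """The requested channel carries no usable signal (e.g. all-achromatic hue)."""


class NoTransitionError(TitracamError):
    """No color-signal jump distinguishable from plateau noise."""


class FitFailureError(TitracamError):
    """The sigmoid fit did not converge or placed the endpoint out of range."""


class CalibrationError(TitracamError):
    """Degenerate calibration input (rank deficiency, zero slope)."""


class RunLoadError(TitracamError):
    """A titration run directory or dose log could not be assembled."""
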