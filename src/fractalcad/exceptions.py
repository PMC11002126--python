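"""Exception hierarchy for the pipeline.

Every error a pipeline stage can raise derives from :class:`FractalCADError`
so callers can distinguish domain failures from programming errors, while
still behaving as ``ValueError`` for argument-validation purposes.
"""


class FractalCADError(ValueError):
    """Base class for all domain errors raised by this package."""


class InvalidParameterError(FractalCADError):
    """An argument is outside its documented domain."""


class DegenerateHistogramError(FractalCADError):
    """The gray-level histogram is unimodal or single-valued, so the
    two-peak threshold rule has no peak on one side of the midpoint."""

    def __init__(self, side: str, message: str | None = None):
        self.side = side
        super().__init__(message or f"no histogram peak on the {side} side of the midpoint")


class EmptyRegionError(FractalCADError):
    """A binary mask contains no foreground pixels."""


class TooSmallRegionError(FractalCADError):
    """The foreground region is too small to carry a contour (< 8 boundary pixels)."""


class TooFewScalesError(FractalCADError):
    """Fewer than three usable box sizes remain for the log-log fit."""


class DegenerateSpectrumError(FractalCADError):
    """The one-sided power spectrum is (numerically) all zero — the radial
    function is constant, i.e. a perfect circle.  Smooth shapes should fall
    back to FD = 1."""


class UndefinedMetricError(FractalCADError):
    """A performance metric has a zero denominator."""

    def __init__(self, metric: str):
        self.metric = metric
        super().__init__(f"{metric} is undefined: zero denominator")


class UndefinedCorrelationError(FractalCADError):
    """Pearson correlation is undefined because one side has zero variance."""


class PipelineStageError(FractalCADError):
    """Wraps a failure inside ``run_pipeline``, recording which stage failed
    and any artifacts produced before the failure."""

    def __init__(self, stage: str, cause: Exception, partial: dict | None = None):
        self.stage = stage
        self.cause = cause
        self.partial = partial or {}
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
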