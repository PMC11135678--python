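"""Exception hierarchy shared across the pipeline stages."""


class CalltagError(Exception):
    """Base class for all calltag errors."""


class InvalidParameterError(CalltagError, ValueError):
    """A numeric parameter is non-finite or outside its legal range."""


class InvalidGeometryError(CalltagError, ValueError):
    """A scene distance matrix is not a valid geometry."""


class InvalidConfigError(CalltagError, ValueError):
    """A configuration is internally inconsistent (e.g. aliasing)."""


class ZeroEnergyError(CalltagError, ValueError):
    """A waveform segment carries no energy."""


class InvalidWindowError(CalltagError, ValueError):
    """A measurement window is empty or lies outside its segment."""


class AmbiguityError(CalltagError, ValueError):
    """Cross-tag matching produced a same-tag collision inside one bundle."""

    def __init__(self, message, collisions=None):
        super().__init__(message)
        self.collisions = collisions or []


class InsufficientDataError(CalltagError, ValueError):
    """Too few observations to estimate the requested quantity."""


class FitFailureError(CalltagError, RuntimeError):
    """An optimizer failed to converge on every start."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateIntervalError(CalltagError, ValueError):
    """Two calls share an onset, producing a zero inter-call interval."""


class ClassificationError(CalltagError, ValueError):
    """A call lacks a feature required by the classification tree."""


class SchemaError(CalltagError, ValueError):
    """An input table is missing required columns."""


class ComparisonError(CalltagError, ValueError):
    """Two model fits are not comparable (different data or method)."""


class RandomEffectError(CalltagError, ValueError):
    """The random-intercept variance is inestimable (single individual)."""
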