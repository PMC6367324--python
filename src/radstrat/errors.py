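"""Exception hierarchy shared across the package."""


class RadstratError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(RadstratError, ValueError):
    """A generator or learner specification violates its invariants."""


class InvalidInputError(RadstratError, ValueError):
    """An input object (image, matrix, prediction set) violates its contract."""


class UndefinedMetricError(RadstratError, ValueError):
    """A metric is requested on data for which it is not defined
    (e.g. AUC on a single-class prediction set)."""


class DegenerateTrainingError(RadstratError, ValueError):
    """Training data cannot support a two-class fit (single class present)."""


class SchemaError(RadstratError, ValueError):
    """Feature names/order of an input table do not match the model manifest."""


class UnsupportedParameterError(RadstratError, ValueError):
    """A parameter lies outside the tabulated/supported range."""
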