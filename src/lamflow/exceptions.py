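"""Shared exception types."""


class LamflowError(Exception):
    """Base class for package errors."""


class DegenerateSeriesError(LamflowError):
    """The input series carries no usable variation (constant or near-constant)."""


class EmbeddingError(LamflowError):
    """The series cannot be embedded with the requested parameters."""


class RadiusSolveError(LamflowError):
    """The fixed-recurrence radius search cannot be performed."""


class PredictionError(LamflowError):
    """The zeroth-order predictor cannot be applied (e.g. too few neighbours)."""
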