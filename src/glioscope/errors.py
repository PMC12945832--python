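"""Shared exception types."""


class GlioscopeError(Exception):
    """Base class for package errors."""


class EvaluationError(GlioscopeError):
    """An objective function returned a non-finite value."""

    def __init__(self, point, value):
        self.point = point
        self.value = value
        super().__init__(
            f"objective returned non-finite value {value!r} at point {point!r}"
        )


class LeakageError(GlioscopeError):
    """Data from outside the training partition reached a train-only step."""


class ChaosStateError(GlioscopeError):
    """Chaotic stream state left its admissible interval."""
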