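"""Exception types shared across the pipeline stages."""


class ThyrometError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(ThyrometError, ValueError):
    """An argument violates a stage precondition."""


class DomainError(ThyrometError, ValueError):
    """A numeric value is outside the mathematical domain of an operation."""


class DegenerateSampleError(ThyrometError, ValueError):
    """A sample cannot be processed (e.g. zero mTIC divisor); names the sample."""

    def __init__(self, sample_id: str, message: str):
        self.sample_id = sample_id
        super().__init__(f"sample {sample_id!r}: {message}")


class StageError(ThyrometError, ValueError):
    """A FeatureTable arrived at an operation in the wrong processing stage."""
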