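"""Exception hierarchy for the ifra package.

Every error raised deliberately by the package derives from :class:`IfraError`
so callers (and the CLI) can distinguish domain failures from bugs.
"""


class IfraError(Exception):
    """Base class for all ifra-specific errors."""


class IngestError(IfraError):
    """A cohort file violates the expected layout or content."""


class DesignError(IfraError):
    """A split design is infeasible for the cohort it is applied to."""


class AugmentationError(IfraError):
    """Minority-class augmentation was requested with impossible parameters."""


class SamplingExhaustedError(IfraError):
    """More distinct balanced subsets were requested than combinatorially exist."""


class EmptySelectionError(IfraError):
    """No subsampled training subset passed the validation-accuracy gate."""


class ScaleError(IfraError):
    """A risk scale could not be built from the given training data."""


class ClassificationError(IfraError):
    """A subject could not be assigned a risk stratum."""


class EvaluationError(IfraError):
    """A contingency table or exact-test input is invalid."""
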