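"""Exception hierarchy for the pipeline.

Every error raised by orscreen derives from :class:`OrscreenError`, so callers
can catch pipeline failures without masking programming errors.
"""


class OrscreenError(Exception):
    """Base class for all orscreen errors."""


class InvalidConfigError(OrscreenError):
    """A generator or analysis configuration violates its invariants."""


class MalformedRecordError(OrscreenError):
    """An input record is structurally invalid (missing reads, sites, ...)."""


class DegenerateReferenceError(OrscreenError):
    """A plate's positive-control signal is zero or negative."""


class DegenerateNormalizationError(OrscreenError):
    """Maximum-signal normalization requested but the maximum is not positive."""


class InsufficientDataError(OrscreenError):
    """Too few observations for the requested statistic."""


class IncompleteValidationError(OrscreenError):
    """A screen hit has no concentration-response validation outcome."""


class UnmatchedMockError(OrscreenError):
    """A test (odorant, concentration) condition has no mock-control wells."""


class UnderdeterminedFitError(OrscreenError):
    """Fewer distinct concentrations than free Hill parameters."""


class UndefinedRatioError(OrscreenError):
    """A fold-ratio denominator amount is zero."""


class DegenerateSampleError(OrscreenError):
    """A headspace sample has a non-positive internal-standard peak area."""


class UnknownVariantError(OrscreenError):
    """A variant or haplotype label is not present in the definitions table."""


class InconsistentCallsError(OrscreenError):
    """No haplotype pair is consistent with the per-site genotype calls."""
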