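"""Exception hierarchy for cohort I/O and model fitting."""


class PaedzError(Exception):
    """Base class for all package-specific errors."""


class CohortSchemaError(PaedzError):
    """A mandatory column is missing or a coefficient file is malformed."""


class CohortParseError(PaedzError):
    """A cell could not be parsed; message names the row and column."""


class CohortValidationError(PaedzError):
    """A record violates a hard invariant; message is row-indexed."""


class EnvelopeError(PaedzError):
    """A regressed SD evaluated non-positive inside the declared envelope."""


class SampleSizeError(PaedzError):
    """Too few complete records to fit a model."""


class FitError(PaedzError):
    """A regression design was singular or a stratum fit failed."""
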