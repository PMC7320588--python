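"""Exception hierarchy shared by all pipeline stages.

Exit-code mapping used by the CLI: :class:`SchemaError` -> 2,
:class:`DegenerateDataError` -> 3, anything else -> 1.
"""


class NeurocohortError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(NeurocohortError):
    """An input value violates a documented invariant (range, sign, label)."""


class MissingDataError(ValidationError):
    """A required field is absent or non-finite; the message names the field."""


class SchemaError(NeurocohortError):
    """A table lacks required columns or references unknown ones."""


class DegenerateDataError(NeurocohortError):
    """Data admit no meaningful statistic (zero variance, singular design...)."""


class DegenerateColumnError(DegenerateDataError):
    """A score column is constant across the cohort; names the subtest."""


class SingularDesignError(DegenerateDataError):
    """A regression design matrix is rank deficient."""


class ConfigurationError(NeurocohortError):
    """A generator or analysis configuration is internally inconsistent."""
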