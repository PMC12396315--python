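"""Exception hierarchy shared across the pipeline stages."""


class LingContactError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(LingContactError):
    """A simulation specification is internally inconsistent."""


class InvalidInputError(LingContactError):
    """An input table or value violates a stage precondition."""


class DegenerateInputError(LingContactError):
    """Input is syntactically valid but carries no usable signal."""


class F3UndefinedError(LingContactError):
    """F3 cannot be computed for a triplet (e.g. target equals a source)."""


class NotConvergedError(LingContactError):
    """A posterior fit failed its MCMC diagnostics and summaries were refused."""


class InvalidSubsetError(LingContactError):
    """A model subset rule left no usable observations."""


class InvalidComparisonError(LingContactError):
    """Model comparison requested across fits with mismatched response rows."""
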