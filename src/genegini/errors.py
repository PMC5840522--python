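"""Exception types shared across the package."""


class GeneGiniError(Exception):
    """Base class for all package errors."""


class ValidationError(GeneGiniError, ValueError):
    """Input violated a documented precondition."""


class UndefinedGiniError(GeneGiniError, ValueError):
    """Gini coefficient requested for an all-zero profile (mean = 0).

    Callers decide whether to skip the gene or propagate a flag; the kernel
    never silently maps this case to 0 or 1.
    """


class EmptyAnalysisError(GeneGiniError, ValueError):
    """An operation was left with no usable genes or samples."""
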