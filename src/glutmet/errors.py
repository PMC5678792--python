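"""Exception hierarchy shared across the pipeline."""


class GlutmetError(Exception):
    """Base class for all package errors."""


class ValidationError(GlutmetError, ValueError):
    """Input violates a documented precondition (shapes, group sizes, ranges)."""


class FormatError(GlutmetError, ValueError):
    """A file does not conform to its declared format (GMT, TSV, YAML)."""


class NotFoundError(GlutmetError, KeyError):
    """Lookup of a process, product, gene, or cohort failed."""

    def __str__(self) -> str:  # KeyError quotes its message; undo that
        return self.args[0] if self.args else ""


class RankDeficiencyError(GlutmetError, ValueError):
    """Design matrix of a regression is rank deficient (collinear predictors)."""


class EstimationError(GlutmetError, RuntimeError):
    """A statistical estimate is undefined for the given data (e.g. all-zero variances)."""
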