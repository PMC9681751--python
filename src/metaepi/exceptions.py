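"""Exception hierarchy for metaepi.

All errors derive from :class:`MetaEpiError` so callers can catch the
package's failures with a single ``except`` clause. Per-meta-analysis
problems inside the pipeline (no contrast, too few clusters) are caught
internally and logged as exclusions rather than aborting a run.
"""


class MetaEpiError(Exception):
    """Base class for all metaepi errors."""


class ValidationError(MetaEpiError, ValueError):
    """Input violates a documented precondition (bad n, inverted CI, ...)."""


class DegenerateInputError(MetaEpiError, ValueError):
    """Input is formally valid but yields a degenerate quantity
    (zero pooled SD, zero-width confidence interval, control group too
    small to split)."""


class InsufficientDataError(MetaEpiError, ValueError):
    """Fewer observations than the estimator requires."""


class NoContrastError(MetaEpiError, ValueError):
    """A binary moderator takes a single value, so its coefficient is
    unidentifiable."""


class InsufficientClustersError(MetaEpiError, ValueError):
    """Cluster-robust variance needs at least two clusters."""


class UnclearDirectionError(MetaEpiError, ValueError):
    """The expected direction of benefit is unknown and no fallback
    alignment policy was supplied."""
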