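"""Package-specific error types."""


class BenzriskError(Exception):
    """Base class for all benzrisk errors."""


class ReferenceGroupError(BenzriskError):
    """No zero-dose group to serve as the relative-risk reference."""


class SaturatedModelError(BenzriskError):
    """Goodness of fit undefined: no residual degrees of freedom."""


class IdentifiabilityError(BenzriskError):
    """More parameters than dose groups can support."""


class ConvergenceError(BenzriskError):
    """Optimizer failed to converge on a usable fit."""


class RankDeficiencyError(BenzriskError):
    """Regression design matrix is rank deficient (e.g. no smokers)."""


class InversionError(BenzriskError):
    """Metabolite-to-air inversion impossible (zero slope)."""


class ConfigError(BenzriskError):
    """Invalid configuration (e.g. infeasible target R-squared)."""
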