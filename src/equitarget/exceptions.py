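"""Exception hierarchy shared across the package.

Every error raised by equitarget derives from :class:`EquitargetError` so
callers (notably the CLI) can distinguish package failures from bugs.
"""


class EquitargetError(Exception):
    """Base class for all equitarget errors."""


class ConfigurationError(EquitargetError):
    """A configuration value violates its invariant; names the offending field."""


class GenerationError(EquitargetError):
    """The synthetic register could not be generated (e.g. a region without CHCs)."""


class PanelConstructionError(EquitargetError):
    """Micro-data could not be aggregated into a complete area-year panel."""


class ValidationError(EquitargetError):
    """An input value is outside its documented domain."""


class NormalizationError(EquitargetError):
    """The national reference composite is degenerate (all-zero mean)."""


class AggregationError(EquitargetError):
    """An area-year group is empty or otherwise unaggregatable."""


class ReferentialIntegrityError(EquitargetError):
    """A foreign key (e.g. a household's CHC id) cannot be resolved."""


class SingularDesignError(EquitargetError):
    """The regression design matrix is rank deficient; lists collinear terms."""


class ClusteringError(EquitargetError):
    """Too few clusters for cluster-robust inference."""


class DegenerateMarginError(EquitargetError):
    """Two-part model outcome is all-zero or all-positive."""


class SeparationError(EquitargetError):
    """Perfect separation detected in the logistic extensive margin."""


class NoTurningPointError(EquitargetError):
    """Quadratic coefficient is (numerically) zero; no turning point exists."""


class UndefinedCIError(EquitargetError):
    """Concentration index undefined (all-zero outcome)."""


class PipelineError(EquitargetError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage
        self.message = message
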