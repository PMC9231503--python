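"""Exception hierarchy shared across the pipeline."""


class GroupRHPError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GroupRHPError, ValueError):
    """A configuration object violates one of its invariants."""


class GenerationError(GroupRHPError, RuntimeError):
    """Synthetic-data generation could not satisfy its constraints."""


class SchemaError(GroupRHPError, ValueError):
    """A table does not match its documented schema."""


class ScalingError(GroupRHPError, ValueError):
    """Predictor scaling is undefined (e.g. a constant column)."""


class ImputationError(GroupRHPError, RuntimeError):
    """Weight imputation failed (empty reference set, ineligible roster...)."""


class FitError(GroupRHPError, RuntimeError):
    """A model fit could not be computed or did not converge."""


class PipelineError(GroupRHPError, RuntimeError):
    """An orchestration-level failure (e.g. no converged candidate models)."""
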