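"""Exception hierarchy for the cfni pipeline.

Every stage raises a subclass of :class:`CfniError`, so callers (the CLI,
``run_pipeline``) can distinguish user-input problems from internal faults
and attach the stage name when propagating.
"""


class CfniError(Exception):
    """Base class for all package errors."""


class SchemaError(CfniError):
    """An input table is missing a required column."""


class ValidationError(CfniError):
    """A row or value violates an invariant (negative weight, bad category...)."""


class ConfigurationError(CfniError):
    """A thresholds or standards config is malformed or incomplete."""


class CalibrationError(CfniError):
    """The generator's moment targets are infeasible."""


class DegenerateCartError(CfniError):
    """A cart contains no ranked food, so tier percentages are undefined."""


class AnalysisError(CfniError):
    """A collection-level computation has no valid input (e.g. all carts degenerate)."""


class UndefinedScoreError(CfniError):
    """HEI densities are undefined because the energy total is zero."""


class SingularDesignError(CfniError):
    """The regression design matrix is rank deficient."""


class PartitionError(CfniError):
    """A fold or quintile partition cannot be formed."""


class SelectionError(CfniError):
    """Penalty selection failed (no finite criterion values)."""


class DegenerateFormulaError(CfniError):
    """All index weights coincide, so the 0-100 rescaling is undefined."""


class PipelineError(CfniError):
    """Wraps a stage failure with the stage name attached."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
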