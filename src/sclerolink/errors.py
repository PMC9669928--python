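"""Exception hierarchy shared across the package."""


class SclerolinkError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(SclerolinkError, ValueError):
    """Input too small or otherwise degenerate for the requested statistic."""


class UndefinedCorrelationError(SclerolinkError, ValueError):
    """Correlation undefined (zero variance in one of the arguments)."""


class DegenerateGroupError(SclerolinkError, ValueError):
    """A group has too few observations for ANOVA / post-hoc analysis."""


class SingularDesignError(SclerolinkError, ValueError):
    """Rank-deficient design matrix in a least-squares fit."""


class UndefinedFitError(SclerolinkError, ValueError):
    """Scale-free topology fit undefined (no spread in connectivity)."""


class InvalidMatrixError(SclerolinkError, ValueError):
    """Matrix fails a structural requirement (square, symmetric, ...)."""


class DegenerateModuleError(SclerolinkError, ValueError):
    """Module too small to summarise by an eigengene."""


class DegenerateOverlapError(SclerolinkError, ValueError):
    """Too few shared samples between two compartments."""


class AmbiguousMappingError(SclerolinkError, ValueError):
    """Identifier map is not one-to-one on the offending identifiers."""


class MissingInputError(SclerolinkError, KeyError):
    """A required analyte / column is absent from the supplied data."""


class DegenerateResponseError(SclerolinkError, ValueError):
    """Response vector is constant; penalised regression is undefined."""


class SchemaError(SclerolinkError, ValueError):
    """A table does not conform to the expected schema."""


class ConfigError(SclerolinkError, ValueError):
    """Invalid configuration values."""


class PipelineHaltedError(SclerolinkError, RuntimeError):
    """A pipeline stage could not proceed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"pipeline halted at stage '{stage}': {message}")
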