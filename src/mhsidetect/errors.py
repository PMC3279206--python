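"""Exception hierarchy shared across the package."""


class MhsiError(Exception):
    """Base class for all package errors."""


class FormatError(MhsiError):
    """A file does not conform to the expected on-disk format."""


class ConsistencyError(MhsiError):
    """Shapes, band counts or metadata disagree between related objects."""


class ParameterError(MhsiError):
    """An argument violates its documented constraints."""


class ConfigurationError(MhsiError):
    """A configuration object is invalid (e.g. an empty training class)."""


class SolverError(MhsiError):
    """A sparse solver failed to converge; carries diagnostics in args."""


class InfeasibleError(SolverError):
    """No coefficient vector satisfies the requested error tolerance."""


class BudgetError(MhsiError):
    """A combinatorial enumeration would exceed its size budget."""


class SplitError(MhsiError):
    """A train/test split cannot be formed (class too small)."""


class EvaluationError(MhsiError):
    """Evaluation is undefined for the given inputs (no labeled pixels)."""


class PipelineError(MhsiError):
    """A pipeline stage failed; the stage name is attached."""
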