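"""Exception hierarchy shared across the package."""


class SourscopeError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(SourscopeError):
    """A generator or pipeline configuration failed validation."""


class MergeError(SourscopeError):
    """Table linkage violated a hard constraint (e.g. duplicate sample codes)."""


class DoughYieldError(SourscopeError):
    """Dough yield is undefined (non-positive flour mass)."""


class VocabularyError(SourscopeError):
    """A categorical label is not in the controlled vocabulary."""


class DegenerateTableError(SourscopeError):
    """A contingency table is too degenerate to test (empty margin, <2x2)."""


class InsufficientDataError(SourscopeError):
    """Not enough non-missing observations for the requested statistic."""


class UndefinedEffectError(SourscopeError):
    """An effect size is undefined (e.g. zero pooled standard deviation)."""


class UndefinedCorrelationError(SourscopeError):
    """A correlation is undefined (zero variance input)."""
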