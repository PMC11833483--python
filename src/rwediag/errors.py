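"""Exception hierarchy for rwediag.

All package-specific failures derive from :class:`RwediagError` so callers
(and the CLI) can catch one base class. Precondition violations on plain
numeric arguments raise :class:`ValueError` directly.
"""


class RwediagError(Exception):
    """Base class for rwediag-specific errors."""


class SchemaError(RwediagError):
    """A table is missing required columns or has an invalid layout."""


class ConfigError(RwediagError):
    """A threshold or run configuration contains unknown or invalid entries."""


class EstimationError(RwediagError):
    """A model fit or effect estimate cannot be computed from the given data."""


class StratificationError(RwediagError):
    """Propensity-score stratification is impossible (too few distinct scores)."""


class AlignmentError(RwediagError):
    """Two tables that must share analysis ids do not align."""
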