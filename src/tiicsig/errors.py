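"""Exception hierarchy shared across the package."""


class TiicError(Exception):
    """Base class for all package errors."""


class CellTableError(TiicError):
    """Malformed or invalid per-cell / clinical table."""


class ConfigurationError(TiicError):
    """Invalid panel, registry, or pipeline configuration."""


class UndefinedDensityError(TiicError):
    """Density requested over a zero pooled area."""


class DegenerateDataError(TiicError):
    """Input too degenerate for the requested statistic (zero variance, empty group, ...)."""


class FitError(TiicError):
    """Model fit failed to converge or produced non-finite estimates."""
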