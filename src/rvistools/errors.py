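"""Exception hierarchy shared across the package.

Three families map onto distinct CLI exit codes: configuration problems,
malformed or inconsistent input data, and statistical degeneracies that make
a requested quantity undefined (e.g. a zero-residual regression fit).
"""


class RvisError(Exception):
    """Base class for all package errors."""


class ConfigError(RvisError):
    """Invalid or incomplete run configuration."""

    exit_code = 2


class InputError(RvisError):
    """Malformed, inconsistent, or empty input data."""

    exit_code = 3


class DegenerateStatisticsError(RvisError):
    """A statistic is undefined for the given data (degenerate design,
    zero residual variance, single-class labels, ...)."""

    exit_code = 4


class DegenerateFitError(DegenerateStatisticsError):
    """Regression fit has zero residual variance; studentization undefined."""


class UndefinedScoreError(DegenerateStatisticsError):
    """A gene's score is undefined (leverage of 1 in the fit)."""
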