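"""Exception hierarchy shared across the package.

``ConfigError`` covers invalid user parameters (bad correlations, unknown
shapes, malformed run configs); ``DataError`` covers problems with input
data files or matrices (non-numeric cells, label mismatches, degenerate
signals). The CLI maps these to exit codes 2 and 3 respectively.
"""


class FcncError(Exception):
    """Base class for all package errors."""


class ConfigError(FcncError):
    """Invalid configuration or parameter values."""


class DataError(FcncError):
    """Invalid or degenerate input data."""


class ZeroVarianceError(DataError):
    """One or more regions have constant signal, so Pearson correlation is undefined."""

    def __init__(self, labels):
        self.labels = list(labels)
        super().__init__(
            "zero-variance regions (Pearson correlation undefined): "
            + ", ".join(self.labels)
        )
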