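"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigurationError -> 2, everything
else derived from LinehrfError -> 1.
"""


class LinehrfError(Exception):
    """Base class for all linehrf errors."""


class ConfigurationError(LinehrfError, ValueError):
    """Invalid or infeasible configuration (bad ISI bounds, odd Fourier order, ...)."""


class DataError(LinehrfError, ValueError):
    """Invalid data passed to an operation (shape mismatch, degenerate sample, ...)."""


class ParseError(DataError):
    """Malformed on-disk input; message carries the offending line number."""


class SingularDesignError(DataError):
    """Rank-deficient GLM design; message names the offending columns."""
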