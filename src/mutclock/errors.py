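"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigurationError and ValidationError
are user-input problems (exit 2); AnalysisError is a computation failure
(exit 3).
"""


class MutclockError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MutclockError):
    """Bad configuration: missing columns, unknown options, absent paths."""


class ValidationError(MutclockError):
    """Input data violates a structural invariant (duplicates, bad Newick)."""


class AnalysisError(MutclockError):
    """A statistical computation cannot proceed (singular matrix, n too small)."""
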