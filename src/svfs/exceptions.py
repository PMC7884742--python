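"""Error hierarchy with CLI exit codes.

Exit-code convention: 0 success, 2 input error, 3 numerical error,
4 empty result (no feature correlates with the label).
"""


class SVFSError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(SVFSError):
    """Malformed or inconsistent user input (bad shapes, NaNs, missing cells)."""

    exit_code = 2


class NumericalError(SVFSError):
    """A numerical routine failed to converge or produced unusable output."""

    exit_code = 3


class EmptyResultError(SVFSError):
    """The pipeline found no feature with any correlation to the label."""

    exit_code = 4


class ConstructionError(InputError):
    """A synthetic-data specification cannot be materialized."""
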