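"""Exception hierarchy.

``DataError`` covers malformed inputs (files, tables, models); it maps to
exit code 2 in the command-line interface.  Usage mistakes (bad flags,
impossible parameter combinations) raise ``UsageError`` or plain
``ValueError`` and map to exit code 1.
"""


class DepcaError(Exception):
    """Base class for all package-specific errors."""


class DataError(DepcaError):
    """Malformed or inconsistent input data (file contents, id mismatches)."""


class UsageError(DepcaError):
    """Invalid parameter combination supplied by the caller."""
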