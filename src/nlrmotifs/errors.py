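"""Exception hierarchy shared across the package.

Two broad classes matter for the CLI exit-code contract: problems with user
input (exit code 2) and problems with models/configuration (exit code 3).
"""


class NlrMotifsError(Exception):
    """Base class for all package errors."""


class InputError(NlrMotifsError):
    """Invalid or malformed user input (sequences, tables, parameters)."""


class ModelError(NlrMotifsError):
    """Model/configuration problems (missing model, version or dimension mismatch)."""
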