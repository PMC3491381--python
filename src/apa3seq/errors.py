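"""Exception hierarchy for the apa3seq pipeline."""


class Apa3SeqError(Exception):
    """Base class for all package errors."""


class ConfigError(Apa3SeqError, ValueError):
    """A configuration field is missing or invalid; the message names the field."""


class InputError(Apa3SeqError, ValueError):
    """Malformed or inconsistent user input (files, tables, gene sets)."""


class BoundsError(Apa3SeqError, IndexError):
    """A genomic coordinate falls outside the reference sequence."""


class UntestableTableError(Apa3SeqError, ValueError):
    """A contingency table cannot be tested (zero expected cell, empty margin)."""
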