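"""Exception hierarchy.

``CorrdockError`` marks user-correctable input problems (bad files, bad
selections, missing residues); anything else escaping the package is an
internal error.
"""


class CorrdockError(Exception):
    """Base class for user-facing errors."""


class ParseError(CorrdockError):
    """A structure, log, or pose file could not be parsed."""


class SelectionError(CorrdockError):
    """A selection expression is malformed."""


class StructureError(CorrdockError):
    """A structural precondition is violated (missing residue/atom, mismatch)."""
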