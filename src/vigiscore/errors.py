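"""Exception hierarchy.

``ValidationError`` signals a problem with the *content* of an input
(duplicate report identifiers, unmatched required columns, empty listings);
``InputError`` signals that an input could not be read at all.  The CLI maps
these to exit codes 1 and 2 respectively.
"""


class VigiscoreError(Exception):
    """Base class for all package errors."""


class ValidationError(VigiscoreError):
    """Input was readable but semantically invalid."""


class InputError(VigiscoreError):
    """Input could not be read (missing file, unparseable format)."""
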