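"""Exception hierarchy shared across the package.

``ValidationError`` covers bad user input (malformed records, contract
violations); ``FormatError`` narrows that to parse failures of on-disk
formats. Plain ``OSError`` is left to propagate for I/O problems.
"""


class ValidationError(ValueError):
    """Input violates a documented precondition or invariant."""


class FormatError(ValidationError):
    """A text input file does not follow its expected layout."""
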