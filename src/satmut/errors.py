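"""Exception types raised on invalid user input."""


class InputError(ValueError):
    """A user-supplied file or parameter is invalid.

    Raised for malformed input files, coordinate violations, unknown
    mutator or sgRNA identifiers, and reference mismatches. The message
    names the offending file, row or position where known.
    """
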