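class MicrostabError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MicrostabError):
    """A file could not be parsed (malformed header, bad Newick, ...)."""


class ValidationError(MicrostabError):
    """An object violates one of its invariants (duplicate IDs, negative
    counts, unknown categorical level, ...)."""
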