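"""Exception hierarchy shared by all intronevo modules."""


class IntronEvoError(Exception):
    """Base class for all package errors."""


class FormatError(IntronEvoError):
    """A file could not be parsed as the expected format."""


class ValidationError(IntronEvoError):
    """Parsed content violates a documented invariant."""


class InferenceError(IntronEvoError):
    """A gene structure could not be inferred under the given settings."""


class AmbiguityError(IntronEvoError):
    """Intron-slot clustering produced an ambiguous assignment."""
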