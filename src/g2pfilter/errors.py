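"""Exception hierarchy shared across the package."""


class G2PError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(G2PError):
    """A file or field does not conform to its expected format."""


class ValidationError(G2PError):
    """An input value violates a documented precondition or vocabulary."""
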