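"""Exception hierarchy shared across modules."""


class MetabosubError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MetabosubError):
    """A file on disk violates its declared format."""


class ValidationError(MetabosubError):
    """An in-memory object or configuration violates an invariant."""


class CoreSelectionError(MetabosubError):
    """No admissible core cluster exists for a gene set."""
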