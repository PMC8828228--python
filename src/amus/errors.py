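"""Exception hierarchy.

All package-raised errors derive from :class:`AmusError` so callers can
catch broadly; validation-type errors also derive from ``ValueError``.
"""


class AmusError(Exception):
    """Base class for all errors raised by this package."""


class DomainError(AmusError, ValueError):
    """An argument is outside its mathematical/physical domain."""


class DegenerateInputError(DomainError):
    """Input is formally valid but makes the requested quantity undefined
    (zero-norm spectrum, single-class labels, constant vector, ...)."""


class ShapeMismatchError(AmusError, ValueError):
    """Array shapes or band counts do not agree."""


class FormatError(AmusError, ValueError):
    """A file's content does not match the expected on-disk format."""


class SchemaError(FormatError):
    """A tabular file is missing required columns or has malformed rows."""
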