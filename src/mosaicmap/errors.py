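"""Exception hierarchy shared across the package."""


class MosaicMapError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MosaicMapError):
    """A file could not be parsed in its declared format."""


class ValidationError(MosaicMapError, ValueError):
    """An in-memory object violates its invariants (non-finite values,
    out-of-range scores, duplicate identifiers, ...)."""


class ConsistencyError(MosaicMapError):
    """Two objects that must agree (e.g. a thickness map and a parcellation
    defined on the same vertex set) do not."""
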