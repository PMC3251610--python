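"""Exception hierarchy shared across the pipeline stages."""


class SnpforgeError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(SnpforgeError, ValueError):
    """A file or record violates its declared on-disk format."""


class IntegrityError(SnpforgeError, ValueError):
    """Inputs are individually well-formed but mutually inconsistent
    (e.g. a read whose read-group sample is absent from the manifest)."""


class DomainError(SnpforgeError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""
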