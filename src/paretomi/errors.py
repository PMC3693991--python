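"""Exception hierarchy shared across the package."""


class ParetomiError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ParetomiError, ValueError):
    """Invalid input values (non-finite coordinates, bad config, ...)."""


class EmptyInputError(ValidationError):
    """An operation that requires a non-empty collection received an empty one."""


class FingerprintError(ValidationError):
    """Malformed fingerprint (wrong width, non-binary characters)."""


class ZeroFingerprintError(FingerprintError):
    """All-zero fingerprint: Tanimoto similarity is undefined (0/0)."""


class MissingDescriptorError(ValidationError):
    """A model requires a descriptor (e.g. logP) the chemical does not carry."""


class TableFormatError(ValidationError):
    """Model-table CSV does not match the declared dialect."""
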