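"""Exception hierarchy shared across the pipeline."""


class SeroprofileError(Exception):
    """Base class for all package errors."""


class SchemaError(SeroprofileError):
    """A required column or field is missing from an input file."""


class ValidationError(SeroprofileError):
    """An input violates a documented invariant (duplicate ids, bad labels...)."""


class DataError(SeroprofileError):
    """Spectral data violates a physical constraint (negative intensity...)."""


class ConfigurationError(SeroprofileError):
    """Analysis parameters or inputs are mutually inconsistent."""


class TrainingError(SeroprofileError):
    """Discriminator training failed (e.g. no significant peaks selected)."""
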