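"""Exception types shared across the pipeline."""


class RtProteomicsError(Exception):
    """Base class for all package errors."""


class ConfigError(RtProteomicsError):
    """A configuration value violates its contract; message names the field."""


class SchemaError(RtProteomicsError):
    """An input table is missing required columns or carries unknown labels."""


class IntegrityError(RtProteomicsError):
    """Input data violates a structural invariant (duplicates, mismatched universes)."""
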