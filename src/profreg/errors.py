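"""Exception types shared across the package."""


class ProfregError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ProfregError, ValueError):
    """Invalid user input: bad arguments, malformed config, schema violations."""


class SchemaError(ValidationError):
    """A delimited-text input does not match the expected schema."""


class DefinitenessError(ValidationError):
    """A matrix that must be symmetric positive-definite is not."""


class DegenerateColumnError(ValidationError):
    """A data column has no usable variation (zero MAD, range or variance)."""


class GenerationError(ProfregError):
    """Synthetic data generation produced an unusable value (e.g. rate overflow)."""
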