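"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Input data or parameters violate a documented precondition."""


class ConfigurationError(ValueError):
    """A run configuration is inconsistent or names an unknown key."""


class DegenerateTrainingError(ValidationError):
    """Dictionary training data carries no usable (nonzero) features."""
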