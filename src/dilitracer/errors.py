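"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Invalid configuration value (image size, ranges, model dims)."""


class LabelingError(ValueError):
    """Unknown or excluded DILI-concern label string."""


class ValidationError(ValueError):
    """Structurally invalid dataset index or image stack."""
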