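"""Exception types shared across the package."""


class KdsigError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(KdsigError, ValueError):
    """A configuration object or file is invalid.

    Carries the complete list of violations, not just the first one.
    """

    def __init__(self, violations):
        if isinstance(violations, str):
            violations = [violations]
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class FormatError(KdsigError, ValueError):
    """An input file does not conform to its declared format."""
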