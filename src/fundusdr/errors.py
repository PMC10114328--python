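"""Exception types shared across the package."""


class FundusDRError(Exception):
    """Base class for package errors."""


class ConfigError(FundusDRError, ValueError):
    """A configuration value violates its contract."""


class InvalidInputError(FundusDRError, ValueError):
    """An input image or dataset violates its contract."""
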