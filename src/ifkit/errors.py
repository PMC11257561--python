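"""Exception types shared across the package."""


class InputError(ValueError):
    """Raised when user-supplied values violate an operation's preconditions."""


class ConfigurationError(RuntimeError):
    """Raised when a combination of settings is internally inconsistent."""
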