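"""Exception hierarchy shared across the package."""


class LungPCMError(Exception):
    """Base class for all package errors."""


class ValidationError(LungPCMError, ValueError):
    """An input object violates its declared invariants."""


class DomainError(LungPCMError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""


class InsufficientDataError(LungPCMError, ValueError):
    """Too few observations to carry out a fit."""


class ConfigurationError(LungPCMError, ValueError):
    """A run configuration is incomplete or inconsistent."""


class ConfigValidationError(ConfigurationError):
    """Aggregated configuration validation failures.

    Carries every failure found, not just the first one.
    """

    def __init__(self, messages):
        self.messages = list(messages)
        super().__init__(
            "configuration invalid (%d problem%s):\n- %s"
            % (len(self.messages), "s" if len(self.messages) != 1 else "",
               "\n- ".join(self.messages))
        )
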