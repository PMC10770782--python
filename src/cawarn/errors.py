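"""Exception taxonomy: configuration vs data vs contract violations."""


class CawarnError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CawarnError):
    """An invalid configuration value; the message names the field."""


class DataError(CawarnError):
    """Malformed or inconsistent input data."""


class ContractError(CawarnError):
    """A broken internal contract, e.g. feature-name mismatch."""
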