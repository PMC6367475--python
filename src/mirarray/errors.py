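"""Exception hierarchy shared across the pipeline stages."""


class MirarrayError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MirarrayError):
    """Invalid or inconsistent configuration (simulation or pipeline)."""


class InputError(MirarrayError):
    """Malformed or inconsistent user input."""


class IntegrityError(MirarrayError):
    """Internal cross-reference violated (e.g. annotation outside its sequence)."""
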