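"""Exception hierarchy mapped to CLI exit codes (0 ok / 1 input / 2 config)."""


class PaddyError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(PaddyError):
    """Malformed or inconsistent data passed to an operation (exit code 1)."""

    exit_code = 1


class ConfigurationError(PaddyError):
    """Invalid configuration or usage (exit code 2)."""

    exit_code = 2
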