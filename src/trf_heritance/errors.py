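"""Exception types shared across the pipeline stages."""


class ParameterError(ValueError):
    """A caller-supplied parameter is outside its documented domain."""


class FormatError(ValueError):
    """An input file or sequence violates its format contract."""


class ContractError(ValueError):
    """Inputs that are individually valid but mutually inconsistent."""


class ConfigError(ValueError):
    """A pipeline configuration is missing or mistypes a required key."""
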