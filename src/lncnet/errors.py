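"""Exception hierarchy shared by all pipeline stages."""


class LncnetError(Exception):
    """Base class for all package errors."""


class FormatError(LncnetError, ValueError):
    """Malformed input file (bad header, bad value, broken convention)."""


class ConsistencyError(LncnetError, ValueError):
    """Inputs are individually valid but mutually inconsistent."""


class ConfigError(LncnetError, ValueError):
    """Invalid analysis or simulation configuration."""


class DegenerateInputError(LncnetError, ValueError):
    """Statistically degenerate input, e.g. a constant expression profile."""
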