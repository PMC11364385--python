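"""Exception hierarchy shared across empflow modules."""


class EmpflowError(Exception):
    """Base class for all empflow errors."""


class StructuralError(EmpflowError, ValueError):
    """Shapes or annotations do not line up (e.g. matrix vs. metadata rows)."""


class ValidationError(EmpflowError, ValueError):
    """Values violate a contract (negative counts, zero library size, ...)."""


class ConfigError(EmpflowError, ValueError):
    """Invalid configuration (thresholds, windows, missing seed, ...)."""


class ParseError(EmpflowError, ValueError):
    """A text input file could not be parsed."""
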