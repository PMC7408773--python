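"""Exception hierarchy shared across the package."""


class LynchlikeError(Exception):
    """Base class for package errors."""


class ValidationError(LynchlikeError, ValueError):
    """Input data violates a documented contract."""


class PedigreeError(ValidationError):
    """Structural problem in a pedigree (dangling parent, cycle, duplicate)."""


class ConfigError(LynchlikeError, ValueError):
    """Invalid or missing configuration (penetrance, LR tables, thresholds)."""
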