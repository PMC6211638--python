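"""Exception types shared across the package."""


class AllelicError(Exception):
    """Base class for package errors."""


class ConfigError(AllelicError):
    """A configuration field is missing or outside its valid range."""


class FormatError(AllelicError):
    """An input table violates its schema (e.g. inconsistent UMI lengths)."""


class PairingError(AllelicError):
    """Bound/unbound results could not be paired one-to-one."""


class EstimationError(AllelicError):
    """An estimator received no usable data."""


class StageError(AllelicError):
    """A pipeline stage failed; the message names the stage."""
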