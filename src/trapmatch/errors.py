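"""Exception types raised across the pipeline."""


class TrapMatchError(Exception):
    """Base class for all package errors."""


class DegeneratePatchError(TrapMatchError):
    """A constant (zero-variance) patch cannot be energy-normalized."""


class DegenerateTemplateError(TrapMatchError):
    """The matching template is constant; normalized correlation is undefined."""


class UndefinedFeaturesError(TrapMatchError):
    """Shape features requested for an empty binary component."""


class UndefinedMetricError(TrapMatchError):
    """A metric's denominator is zero (e.g. precision with TP + FP = 0)."""


class SceneError(TrapMatchError):
    """A synthetic-scene specification cannot be rendered as requested."""


class ConfigError(TrapMatchError):
    """A pipeline configuration value is invalid; message names the field."""
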