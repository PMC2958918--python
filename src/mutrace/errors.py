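"""Exception hierarchy for mutrace."""


class MutraceError(Exception):
    """Base class for all mutrace errors."""


class InvalidParameterError(MutraceError, ValueError):
    """A configuration or function argument violates a model invariant."""


class InconsistencyError(MutraceError, RuntimeError):
    """Internal state inconsistency (e.g. a label without an assigned rate)."""


class ExtinctionError(MutraceError, RuntimeError):
    """Total population fitness reached zero; no offspring can be sampled."""


class FertilityError(MutraceError, RuntimeError):
    """The fertility cap makes it impossible to fill all offspring slots."""


class ConfigError(InvalidParameterError):
    """A configuration file or mapping failed schema validation."""
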