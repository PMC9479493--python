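"""Exception hierarchy for dtipower."""


class DtiPowerError(Exception):
    """Base class for all dtipower errors."""


class InvalidInputError(DtiPowerError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateDataError(DtiPowerError, ValueError):
    """The input carries no usable variance (e.g. all cells identical)."""


class ConfigError(DtiPowerError, ValueError):
    """A configuration file or override is malformed; the message names the key."""


class SampleSizeNotReachedError(DtiPowerError, RuntimeError):
    """A sample-size search did not reach the power target within its bounds."""
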