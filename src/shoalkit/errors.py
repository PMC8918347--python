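"""Exception hierarchy."""


class ShoalkitError(Exception):
    """Base class for all shoalkit errors."""


class TrajectoryParseError(ShoalkitError):
    """A trajectory file violates the CSV dialect or its invariants."""


class ConfigurationError(ShoalkitError):
    """Missing or inconsistent metadata / configuration."""


class UndefinedStatisticError(ShoalkitError):
    """A statistic is undefined for the given input (e.g. zero variance,
    all samples missing, fewer than two tracked frames)."""
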