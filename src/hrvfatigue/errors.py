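"""Exceptions shared across the pipeline."""


class HrvFatigueError(Exception):
    """Base class for package errors."""


class ConfigurationError(HrvFatigueError):
    """A configuration value is inconsistent or out of range."""


class InsufficientDataError(HrvFatigueError):
    """Too few records to compute the requested statistic."""


class SchemaError(HrvFatigueError):
    """A file does not conform to the expected tabular schema."""
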