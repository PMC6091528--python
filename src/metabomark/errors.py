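"""Exception hierarchy shared across the pipeline stages."""


class MetabomarkError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(MetabomarkError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class DataError(MetabomarkError, ValueError):
    """Input data violates a stage precondition (e.g. zero-sum sample row)."""
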