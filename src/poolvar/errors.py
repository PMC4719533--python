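"""Exception hierarchy shared across the pipeline."""


class PoolvarError(Exception):
    """Base class for all poolvar errors."""


class FormatError(PoolvarError):
    """A file did not conform to its declared on-disk format."""


class ConfigError(PoolvarError):
    """A run configuration is unreadable, incomplete or type-invalid."""


class StepError(PoolvarError):
    """A pipeline step failed at run time."""
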