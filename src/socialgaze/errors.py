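"""Exception hierarchy shared across the package."""


class SocialGazeError(Exception):
    """Base class for all package errors."""


class FormatError(SocialGazeError):
    """A file does not conform to the declared dialect (e.g. missing column)."""


class DataError(SocialGazeError):
    """The file parsed but its contents violate an invariant (e.g. time order)."""


class ConfigError(SocialGazeError):
    """Invalid configuration: overlapping schedule entries, bad windows, etc."""


class EstimationError(SocialGazeError):
    """An estimator has no usable input (e.g. no fixations for offset search)."""
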