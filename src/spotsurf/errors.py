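"""Exception hierarchy for the spotsurf pipeline."""


class SpotSurfError(Exception):
    """Base class for all spotsurf errors."""


class DomainError(SpotSurfError):
    """An input violates a precondition of the operation (geometry, bounds,
    empty masks, infeasible parameter combinations)."""


class ConfigError(SpotSurfError):
    """A configuration value is out of range or a config file is malformed."""


class DetectionError(SpotSurfError):
    """Segmentation or detection produced no usable object."""
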