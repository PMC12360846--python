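"""Exception hierarchy shared across the package."""


class MapganError(Exception):
    """Base class for all package errors."""


class MapFormatError(MapganError):
    """A volume file violates the MRC2014 layout; the message names the field."""


class UnsupportedModeError(MapFormatError):
    """The MRC mode word does not describe a scalar volume we can read."""


class ModelParseError(MapganError):
    """An atomic-model file could not be interpreted."""


class EmptyModelError(MapganError):
    """An operation that needs atoms received a model with none."""


class UndefinedMetricError(MapganError):
    """A similarity metric is undefined for the given inputs (e.g. constant map)."""


class ConfigError(MapganError):
    """A network/run configuration is internally inconsistent."""
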