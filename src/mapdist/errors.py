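"""Exception hierarchy for mapdist."""


class MapDistError(Exception):
    """Base class for all mapdist errors."""


class MapFormatError(MapDistError):
    """A volume file could not be read or is not a 3-D metric map."""


class ConfigError(MapDistError):
    """A manifest, suite file, or term configuration is malformed."""


class ValidationError(MapDistError):
    """Inputs violate an operation's contract (shapes, ids, normalization)."""


class EmptyHistogramError(MapDistError):
    """A map has no voxels inside the histogram range; it cannot be compared."""
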