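"""Exception hierarchy for the rnfllab pipeline."""


class RnflLabError(Exception):
    """Base class for all rnfllab errors."""


class LandmarkGeometryError(RnflLabError):
    """Eye landmarks (fovea, disc, bundle angles) violate anatomical constraints."""


class GridMismatchError(RnflLabError):
    """Two maps (or a map and a model) do not share grid shape / pixel size."""


class InsufficientReferenceError(RnflLabError):
    """Too few reference eyes (or values) to build a normative quantity."""


class MetadataError(RnflLabError):
    """Required map metadata (view tag, laterality, landmarks) is missing."""


class ConfigurationError(RnflLabError):
    """Invalid cohort / experiment / rule configuration."""


class InsufficientDataError(RnflLabError):
    """Not enough visual-field records to apply a longitudinal criterion."""
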