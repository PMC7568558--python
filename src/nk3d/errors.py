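"""Exception types shared across the pipeline."""


class NK3DError(Exception):
    """Base class for all nk3d errors."""


class InvalidConfigError(NK3DError, ValueError):
    """A configuration value violates its contract (e.g. nonpositive duration)."""


class MissingMetadataError(NK3DError, ValueError):
    """An image or frame lacks the calibration metadata required to analyse it."""


class InvalidAssayError(NK3DError, ValueError):
    """Assay control values are inconsistent (e.g. maximum <= spontaneous release)."""


class UndefinedStatisticError(NK3DError, ValueError):
    """The requested statistic is undefined for the given input."""
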