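"""Exception hierarchy for the microwell patterning pipeline."""


class WellpatError(Exception):
    """Base class for all package errors."""


class GeometryError(WellpatError):
    """Array geometry is inconsistent (e.g. wells would overlap)."""


class EmptyLayoutError(GeometryError):
    """Footprint too small to hold a single well."""


class ConfigError(WellpatError):
    """Invalid configuration value (probabilities, densities, schema)."""


class ResolutionError(WellpatError):
    """Pixel scale too coarse to resolve the requested feature."""


class TemplateSizeError(WellpatError):
    """Template does not fit inside the search image."""


class DegenerateTemplateError(WellpatError):
    """Template has zero intensity variance; correlation undefined."""


class SamplingError(WellpatError):
    """Requested more wells than were detected."""


class DegenerateThresholdError(WellpatError):
    """Image is constant or saturated; no threshold separates signal."""


class AssignmentError(WellpatError):
    """Nearest-well assignment against an empty well set."""


class UndefinedStatisticError(WellpatError):
    """Statistic has an empty denominator (zero cells / zero ratio base)."""


class DegenerateVarianceError(WellpatError):
    """Pooled variance is zero; t statistic undefined."""
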