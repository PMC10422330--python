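"""Exception hierarchy for the reef3d pipeline."""


class ReefError(Exception):
    """Base class for all reef3d errors."""


class FormatError(ReefError):
    """A file's content violates the expected raster/cloud/mesh contract."""


class CoregistrationError(ReefError):
    """Two rasters that must share a grid do not."""


class GenerationError(ReefError):
    """Synthetic-scene generation could not satisfy its constraints."""


class ParameterError(ReefError):
    """A parameter value is outside its documented domain."""


class TilingError(ReefError):
    """Patch extraction or stitching is impossible for the given extent."""


class TerrainError(ReefError):
    """A terrain derivative (slope, VRM) cannot be computed on this grid."""


class MeshError(ReefError):
    """Mesh construction failed (too few valid cells)."""


class MetricError(ReefError):
    """A segmentation metric is undefined (no valid pixels)."""


class StatsError(ReefError):
    """A summary statistic is requested over an empty selection."""


class TrainingError(ReefError):
    """Training diverged or was configured inconsistently."""
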