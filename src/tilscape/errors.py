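"""Exception hierarchy for the tilscape pipeline.

Every error raised on a per-slide basis derives from :class:`TilscapeError`
so batch drivers can catch one type, flag the slide, and move on.
"""


class TilscapeError(Exception):
    """Base class for all tilscape errors."""


class FormatError(TilscapeError):
    """Malformed input file (ragged CSV, unsupported image mode, ...)."""


class ValidationError(TilscapeError):
    """Input violates a documented invariant (probabilities outside [0,1],
    unequal rater counts, ...)."""


class ParameterError(TilscapeError):
    """A caller-supplied parameter is outside its legal domain."""


class AlignmentError(TilscapeError):
    """Tumor and lymphocyte grids cannot be placed on a common lattice."""


class UndefinedFeatureError(TilscapeError):
    """A spatial feature or summary is undefined for this map (e.g. the
    tumor mask is empty); the slide should be flagged, not silently scored."""


class GenerationError(TilscapeError):
    """A synthetic-data spec produced a degenerate object (empty tumor mask)."""
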