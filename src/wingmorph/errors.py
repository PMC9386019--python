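"""Exception hierarchy shared across the pipeline."""


class WingmorphError(Exception):
    """Base class for all package-specific errors."""


class ImageFormatError(WingmorphError):
    """File could not be read as a supported raster image (PNG/TIFF/JPEG)."""


class DegenerateImageError(WingmorphError):
    """Image content does not support the requested operation (e.g. constant intensity)."""


class InvalidSeedError(WingmorphError):
    """A seed pixel does not satisfy the operation's precondition."""


class NoWingFoundError(WingmorphError):
    """No wing silhouette could be detected in the image."""


class TracingError(WingmorphError):
    """Boundary pixel set cannot be traced as a single closed contour."""

    def __init__(self, message, components=None):
        super().__init__(message)
        self.components = components or []


class DegenerateInputError(WingmorphError):
    """Geometric input too small or degenerate for the operation."""


class AssemblyError(WingmorphError):
    """Model assembly failed (e.g. missing boundary for a detected region)."""


class GenerationError(WingmorphError):
    """Synthetic fixture generation failed under the requested parameters."""
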