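"""Image loading, binarisation and input-quality screening.

Conventions used throughout the package:

* A *raster image* is a 2-D ``numpy.uint8`` array of intensities in [0, 255],
  indexed ``[row, col]`` with row 0 at the top.
* A *binary image* is a 2-D boolean array where ``True`` is white.  White is
  the membrane/cell foreground that region growing floods; veins and other
  dark structures are ``False`` (black).  Images with the opposite polarity
  should be inverted by the caller (the CLI exposes ``--invert``).

Quality screening is advisory: wings photographed faded, dark, noisy or with
hairline venation degrade region extraction, so :func:`assess_quality` raises
warnings flags but never refuses an image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from .errors import DegenerateImageError, ImageFormatError

SUPPORTED_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}

#: Default thresholds for the four advisory quality flags.
QUALITY_DEFAULTS = {
    "faded_contrast_span": 80.0,   # robust intensity span below which the image is "faded"
    "dark_mean": 60.0,             # mean intensity below which the image is "dark"
    "salt_pepper_fraction": 0.01,  # isolated-extreme pixel fraction above which noise is flagged
    "thin_line_width": 2.0,        # median stroke width (px) below which venation is "thin"
}


@dataclass
class QualityReport:
    """Advisory screening result: which suitability criteria an image fails."""

    flags: set = field(default_factory=set)
    metrics: dict = field(default_factory=dict)

    def __bool__(self):  # truthy when clean
        return not self.flags


def load_image(path) -> np.ndarray:
    """Load a PNG/TIFF/JPEG file as an 8-bit grayscale array.

    Colour images are converted by ITU-R 601 luminance; 16-bit TIFFs are
    rescaled to 8 bits.  Raises :class:`ImageFormatError` for unreadable or
    unsupported files.
    """
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"no such file: {path}")
    if path.suffix.lower() not in SUPPORTED_SUFFIXES:
        raise ImageFormatError(
            f"unsupported format {path.suffix!r}: expected PNG, TIFF or JPEG"
        )
    try:
        with Image.open(path) as im:
            if im.mode in ("I", "I;16", "I;16B", "I;16L"):
                arr = np.asarray(im, dtype=np.float64)
                arr = arr / 257.0 if arr.max() > 255 else arr
                return np.clip(np.round(arr), 0, 255).astype(np.uint8)
            if im.mode != "L":
                im = im.convert("L")
            return np.asarray(im, dtype=np.uint8)
    except UnidentifiedImageError as exc:
        raise ImageFormatError(f"cannot read {path} as a raster image") from exc


def save_image(img: np.ndarray, path) -> None:
    """Write a grayscale or binary array as an 8-bit PNG for inspection."""
    Image.fromarray(to_uint8(img)).save(path)


def to_uint8(img: np.ndarray) -> np.ndarray:
    """Coerce a binary (bool) or grayscale array to uint8 with white = 255."""
    img = np.asarray(img)
    if img.dtype == bool:
        return np.where(img, np.uint8(255), np.uint8(0))
    return img.astype(np.uint8)


def binarize(img: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Threshold a grayscale image into a white/black boolean array.

    Pixels with intensity >= *threshold* become white (``True``).  When
    *threshold* is omitted it is chosen automatically by Otsu's
    between-class-variance criterion.  A constant-intensity image has no
    automatic threshold and raises :class:`DegenerateImageError`.
    """
    img = np.asarray(img)
    if img.size == 0:
        raise DegenerateImageError("empty image")
    if img.dtype == bool:
        return img.copy()
    if threshold is None:
        if img.min() == img.max():
            raise DegenerateImageError(
                "constant-intensity image: supply an explicit threshold"
            )
        threshold = threshold_otsu(img)
        # threshold_otsu follows the `img > t` convention; shift by the grid
        # step so that `img >= t` selects the identical partition.
        threshold = float(threshold) + 0.5
    return img >= threshold


def assess_quality(img: np.ndarray, thresholds: dict | None = None) -> QualityReport:
    """Screen an image against the four input-suitability criteria.

    Returns advisory flags only; processing is never blocked.  Flags:

    ``faded``
        robust intensity span (2nd..98th percentile) below
        ``faded_contrast_span`` levels.
    ``dark``
        mean intensity below ``dark_mean``.
    ``salt_pepper_noise``
        fraction of pixels differing from their 3x3 median by >= 100 levels
        exceeds ``salt_pepper_fraction``.
    ``thin_lines``
        median dark-stroke width under ``thin_line_width`` px (hairline
        venation cannot separate neighbouring cells reliably).
    """
    img = np.asarray(to_uint8(img))
    if img.size == 0:
        raise DegenerateImageError("empty image")
    cfg = dict(QUALITY_DEFAULTS)
    if thresholds:
        cfg.update(thresholds)

    report = QualityReport()
    lo, hi = np.percentile(img, [2, 98])
    report.metrics["contrast_span"] = float(hi - lo)
    if hi - lo < cfg["faded_contrast_span"]:
        report.flags.add("faded")

    mean = float(img.mean())
    report.metrics["mean_intensity"] = mean
    if mean < cfg["dark_mean"]:
        report.flags.add("dark")

    med = ndimage.median_filter(img, size=3)
    isolated = np.abs(img.astype(np.int16) - med.astype(np.int16)) >= 100
    frac = float(isolated.mean())
    report.metrics["isolated_extreme_fraction"] = frac
    if frac > cfg["salt_pepper_fraction"]:
        report.flags.add("salt_pepper_noise")

    width = _median_stroke_width(img)
    report.metrics["median_stroke_width"] = width
    if np.isfinite(width) and width < cfg["thin_line_width"]:
        report.flags.add("thin_lines")

    return report


def _median_stroke_width(img: np.ndarray) -> float:
    """Median width (px) of dark strokes: 2x the distance transform sampled
    on the stroke skeleton.  NaN when the image has no dark structure."""
    try:
        dark = ~binarize(img)
    except DegenerateImageError:
        return float("nan")
    if not dark.any() or dark.all():
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        skel = skeletonize(dark)
    if not skel.any():
        return float("nan")
    # a stroke of width w has EDT ~ (w + 1) / 2 at its centreline
    edt = ndimage.distance_transform_edt(dark)
    return float(np.median(2.0 * edt[skel] - 1.0))
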