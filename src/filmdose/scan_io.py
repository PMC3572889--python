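"""Reading, writing and slicing flatbed-scanner film images.

Films are scanned in 48-bit RGB mode (16 bits per channel) and saved as
uncompressed TIFF. The dose-bearing signal lives in the red channel; all
downstream densitometry works on 2-D red-channel maps with a physical pixel
spacing derived from the scan resolution.

Axis convention (used by every direction-tagged statistic downstream):
the first array index runs along the *longitudinal* direction — the
direction of travel of the scan head — and the second index along the
*transverse* direction, orthogonal to it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import BoundsError, DimensionError, FormatError

logger = logging.getLogger(__name__)

#: Scan resolution assumed when a file carries no resolution metadata.
DEFAULT_DPI = 100.0

MM_PER_INCH = 25.4


@dataclass
class FilmImage:
    """A raw multi-channel scan of one film piece.

    Parameters
    ----------
    pixels : ndarray, shape (rows, cols, 3)
        RGB pixel values. Normally uint16 (48-bit scan); float arrays in
        [0, 65535] are accepted for unquantized synthetic renders.
    dpi : float
        Scan resolution in dots per inch.
    """

    pixels: np.ndarray
    dpi: float = DEFAULT_DPI

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            nchan = 1 if self.pixels.ndim == 2 else self.pixels.shape[-1]
            raise FormatError(
                f"expected a 3-channel RGB image, got {nchan} channel(s)")
        if self.pixels.shape[0] < 2 or self.pixels.shape[1] < 2:
            raise FormatError(
                f"image too small: shape {self.pixels.shape[:2]}")
        if self.dpi <= 0:
            raise FormatError(f"dpi must be positive, got {self.dpi}")
        if self.pixels.min() < 0 or self.pixels.max() > 65535:
            raise FormatError("pixel values must lie in [0, 65535]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def orientation(self) -> str:
        """'landscape' when the transverse (second) extent is not larger."""
        rows, cols = self.shape
        return "landscape" if cols <= rows else "portrait"

    @property
    def pixel_spacing_mm(self) -> float:
        return MM_PER_INCH / self.dpi


@dataclass
class ChannelMap:
    """A single-channel 2-D intensity map on a physical grid."""

    values: np.ndarray
    pixel_spacing_mm: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError(f"expected a 2-D map, got {self.values.ndim}-D")
        if self.pixel_spacing_mm <= 0:
            raise FormatError("pixel_spacing_mm must be positive")
        if np.any(self.values < 0):
            raise FormatError("channel values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class ROI:
    """Half-open pixel-index rectangle [row_start, row_stop) x [col_start, col_stop)."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self) -> None:
        if not (0 <= self.row_start < self.row_stop
                and 0 <= self.col_start < self.col_stop):
            raise BoundsError(f"degenerate ROI {self}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_stop - self.row_start, self.col_stop - self.col_start)

    def validate(self, shape: tuple[int, int]) -> None:
        if self.row_stop > shape[0] or self.col_stop > shape[1]:
            raise BoundsError(
                f"ROI {self} exceeds image extent {shape}")

    @classmethod
    def centered_cm(cls, shape: tuple[int, int], pixel_spacing_mm: float,
                    size_cm: tuple[float, float]) -> "ROI":
        """Centered ROI of a requested physical size.

        ``size_cm`` is (longitudinal, transverse) extent in cm; sizes are
        converted to the nearest whole pixel count.
        """
        n_rows = round(size_cm[0] * 10.0 / pixel_spacing_mm)
        n_cols = round(size_cm[1] * 10.0 / pixel_spacing_mm)
        if n_rows > shape[0] or n_cols > shape[1]:
            raise BoundsError(
                f"requested {size_cm} cm ROI ({n_rows}x{n_cols} px) larger "
                f"than image {shape}")
        r0 = (shape[0] - n_rows) // 2
        c0 = (shape[1] - n_cols) // 2
        return cls(r0, r0 + n_rows, c0, c0 + n_cols)

    @classmethod
    def with_margin_mm(cls, shape: tuple[int, int], pixel_spacing_mm: float,
                       margin_mm: float = 2.0) -> "ROI":
        """Full extent minus a fixed edge margin (film-edge exclusion)."""
        m = math.ceil(margin_mm / pixel_spacing_mm)
        roi = cls(m, shape[0] - m, m, shape[1] - m)
        roi.validate(shape)
        return roi


def read_scan(path) -> FilmImage:
    """Read a TIFF film scan into a :class:`FilmImage`.

    The dpi is taken from the file's resolution tags; when absent, the
    conventional 100 dpi scan resolution is assumed (with a warning).
    """
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            pixels = page.asarray()
            dpi = _dpi_from_tags(page)
    except FormatError:
        raise
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder errors vary by backend
        raise OSError(f"cannot read scan {path!r}: {exc}") from exc
    if dpi is None:
        logger.warning("no resolution metadata in %s; assuming %g dpi",
                       path, DEFAULT_DPI)
        dpi = DEFAULT_DPI
    return FilmImage(pixels=pixels, dpi=dpi)


def _dpi_from_tags(page) -> float | None:
    tag = page.tags.get("XResolution")
    if tag is None:
        return None
    value = tag.value
    if isinstance(value, tuple):
        num, den = value
        if den == 0:
            return None
        value = num / den
    unit = page.tags.get("ResolutionUnit")
    # TIFF units: 1 = none (aspect only), 2 = inch (default), 3 = cm
    unit_value = (getattr(unit.value, "value", unit.value)
                  if unit is not None else 2)
    if unit_value == 1:
        return None
    if unit_value == 3:
        value = value * 2.54
    return float(value) if value > 0 else None


def write_scan(path, image: FilmImage) -> None:
    """Write a :class:`FilmImage` as uncompressed 16-bit-per-channel TIFF."""
    pixels = np.asarray(image.pixels)
    if not np.issubdtype(pixels.dtype, np.unsignedinteger):
        pixels = np.clip(np.rint(pixels), 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        path, pixels.astype(np.uint16), photometric="rgb",
        compression=None,
        resolution=(image.dpi, image.dpi), resolutionunit="INCH")


def extract_red(image: FilmImage) -> ChannelMap:
    """Select the red channel — the channel in which the film response
    is strongest — as a physical 2-D map."""
    return ChannelMap(values=image.pixels[:, :, 0].astype(float),
                      pixel_spacing_mm=image.pixel_spacing_mm)


def average_scans(scans: list[ChannelMap]) -> ChannelMap:
    """Pixel-wise mean of repeated scans of the same film.

    Averaging happens in raw pixel space, before the (nonlinear) optical
    density transform.
    """
    if len(scans) == 0:
        raise DimensionError("need at least one scan to average")
    first = scans[0]
    for s in scans[1:]:
        if s.shape != first.shape:
            raise DimensionError(
                f"scan shapes disagree: {first.shape} vs {s.shape}")
        if not math.isclose(s.pixel_spacing_mm, first.pixel_spacing_mm):
            raise DimensionError("scan pixel spacings disagree")
    stacked = np.stack([s.values for s in scans])
    return ChannelMap(values=stacked.mean(axis=0),
                      pixel_spacing_mm=first.pixel_spacing_mm)


def crop_roi(cmap: ChannelMap, roi: ROI) -> ChannelMap:
    """Extract an ROI as a new map with preserved spacing."""
    roi.validate(cmap.shape)
    return ChannelMap(
        values=cmap.values[roi.row_start:roi.row_stop,
                           roi.col_start:roi.col_stop].copy(),
        pixel_spacing_mm=cmap.pixel_spacing_mm)
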