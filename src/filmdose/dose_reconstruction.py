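"""From net optical density to calibrated 2-D dose maps and isodose lines.

Physical coordinates: a :class:`DoseMap` lives on a regular grid with
``origin_mm`` the coordinate of the corner of pixel (0, 0); the center of
pixel (i, j) sits at ``origin_mm + ((i + 0.5) * s, (j + 0.5) * s)`` with
``s`` the pixel spacing. Contour vertices are emitted in these mm
coordinates, first axis longitudinal, second transverse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter
from skimage import measure

from .calibration import CalibrationModel
from .densitometry import NODMap
from .errors import DomainError, FormatError
from .scan_io import ChannelMap

logger = logging.getLogger(__name__)


@dataclass
class DoseMap:
    """Calibrated 2-D dose in Gy on a physical grid."""

    values: np.ndarray
    pixel_spacing_mm: float
    origin_mm: tuple[float, float] = (0.0, 0.0)
    #: pixels whose raw calibrated dose was negative and was clamped to 0
    n_clamped: int = 0
    #: pixels whose NOD fell outside the calibration range
    n_out_of_range: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("dose map must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise DomainError("dose map contains non-finite values")
        if np.any(self.values < 0):
            raise DomainError("dose map contains negative doses "
                              "(clamp at construction)")
        if self.pixel_spacing_mm <= 0:
            raise FormatError("pixel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def axes_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical center coordinates of rows and columns."""
        s = self.pixel_spacing_mm
        rows = self.origin_mm[0] + (np.arange(self.shape[0]) + 0.5) * s
        cols = self.origin_mm[1] + (np.arange(self.shape[1]) + 0.5) * s
        return rows, cols

    def plot(self, ax=None, levels=None, **imshow_kw):
        """Render the dose map (and optional isodose lines) with matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        rows, cols = self.axes_mm()
        extent = [cols[0] - self.pixel_spacing_mm / 2,
                  cols[-1] + self.pixel_spacing_mm / 2,
                  rows[-1] + self.pixel_spacing_mm / 2,
                  rows[0] - self.pixel_spacing_mm / 2]
        im = ax.imshow(self.values, extent=extent, **imshow_kw)
        ax.set_xlabel("transverse position (mm)")
        ax.set_ylabel("longitudinal position (mm)")
        if levels is not None:
            for contour in extract_isodose(self, levels):
                ax.plot(contour.vertices[:, 1], contour.vertices[:, 0],
                        lw=0.8, label=f"{contour.level_gy:g} Gy")
        plt.colorbar(im, ax=ax, label="dose (Gy)")
        return ax


@dataclass(frozen=True)
class IsodoseContour:
    """One level-tagged polyline in physical mm coordinates."""

    level_gy: float
    vertices: np.ndarray  # (n, 2): (longitudinal mm, transverse mm)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        object.__setattr__(self, "vertices", v)
        if self.level_gy <= 0:
            raise DomainError("contour level must be positive")
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise FormatError("contour needs >= 2 (x, y) vertices")

    @property
    def is_closed(self) -> bool:
        return bool(np.allclose(self.vertices[0], self.vertices[-1]))


def wiener_filter(data, window: int = 5, noise_power: float | None = None):
    """Adaptive local-statistics (Wiener) noise filter.

    With m and v the local mean and variance over a ``window``-sized
    square neighbourhood (symmetric-reflection edge handling) and v_n the
    noise power — by default the global mean of the local variances — the
    output is

        m + max(v - v_n, 0) / v * (input - m),

    i.e. flat regions collapse to their local mean while structure whose
    local variance exceeds the noise floor is preserved. Pixels with zero
    local variance return the local mean.

    Accepts a bare 2-D array, a :class:`~filmdose.scan_io.ChannelMap`, an
    OD/NOD map or a :class:`DoseMap`, and returns the same type.
    """
    if isinstance(data, DoseMap):
        out = wiener_filter(data.values, window, noise_power)
        return DoseMap(values=np.clip(out, 0, None),
                       pixel_spacing_mm=data.pixel_spacing_mm,
                       origin_mm=data.origin_mm,
                       n_clamped=data.n_clamped,
                       n_out_of_range=data.n_out_of_range)
    if isinstance(data, (NODMap,)):
        return NODMap(values=wiener_filter(data.values, window, noise_power),
                      pixel_spacing_mm=data.pixel_spacing_mm)
    if isinstance(data, ChannelMap):
        return ChannelMap(values=wiener_filter(data.values, window, noise_power),
                          pixel_spacing_mm=data.pixel_spacing_mm)

    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise FormatError("wiener_filter expects a 2-D map")
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if window >= min(x.shape):
        raise ValueError(
            f"window {window} not smaller than map extents {x.shape}")

    m = uniform_filter(x, size=window, mode="reflect")
    v = uniform_filter(x * x, size=window, mode="reflect") - m * m
    v = np.clip(v, 0.0, None)
    if noise_power is None:
        noise_power = float(v.mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.where(v > 0, np.clip(v - noise_power, 0.0, None) / v, 0.0)
    return m + gain * (x - m)


def to_dose(nod: NODMap, model: CalibrationModel,
            origin_mm: tuple[float, float] = (0.0, 0.0)) -> DoseMap:
    """Apply the calibration curve elementwise to a NOD map.

    Negative calibrated doses (the curve does not pass through the
    origin) are clamped to 0 Gy; the clamp count and the count of pixels
    whose NOD fell outside the calibrated range are recorded on the map
    and logged.
    """
    lo, hi = model.nod_range
    x = nod.values
    n_out = int(np.sum((x < lo) | (x > hi)))
    raw = model.dose(x, warn_extrapolation=False)
    n_clamped = int(np.sum(raw < 0))
    if n_clamped:
        logger.info("clamped %d negative dose pixel(s) to 0 Gy", n_clamped)
    if n_out:
        logger.info("%d NOD pixel(s) outside calibrated range [%g, %g]",
                    n_out, lo, hi)
    return DoseMap(values=np.clip(raw, 0.0, None),
                   pixel_spacing_mm=nod.pixel_spacing_mm,
                   origin_mm=origin_mm,
                   n_clamped=n_clamped, n_out_of_range=n_out)


def extract_isodose(dose_map: DoseMap,
                    levels) -> list[IsodoseContour]:
    """Marching-squares isodose lines with linear edge interpolation.

    One :class:`IsodoseContour` per connected polyline per level, vertices
    in physical mm. Levels outside the map's (min, max) produce no contour
    (with a warning) rather than an error.
    """
    if np.isscalar(levels):
        levels = [levels]
    out: list[IsodoseContour] = []
    s = dose_map.pixel_spacing_mm
    vmin, vmax = float(dose_map.values.min()), float(dose_map.values.max())
    for level in levels:
        level = float(level)
        if level <= 0:
            raise DomainError(f"contour level must be positive, got {level}")
        if not (vmin < level < vmax):
            logger.warning("isodose level %g Gy outside map range "
                           "(%.3g, %.3g); no contour", level, vmin, vmax)
            continue
        for poly in measure.find_contours(dose_map.values, level):
            if poly.shape[0] < 2:
                continue
            vertices = np.column_stack([
                dose_map.origin_mm[0] + (poly[:, 0] + 0.5) * s,
                dose_map.origin_mm[1] + (poly[:, 1] + 0.5) * s,
            ])
            out.append(IsodoseContour(level_gy=level, vertices=vertices))
    return out


def reconstruct_dose(background_scans, exposed_scans,
                     model: CalibrationModel,
                     apply_wiener: bool = False, wiener_window: int = 5,
                     origin_mm: tuple[float, float] = (0.0, 0.0)) -> DoseMap:
    """Full measurement pipeline: scans -> averaged red channel -> NOD ->
    (optional Wiener filter) -> calibrated dose map.

    ``background_scans`` and ``exposed_scans`` are lists of
    :class:`~filmdose.scan_io.FilmImage` (or red-channel
    :class:`~filmdose.scan_io.ChannelMap`) of the same film before and
    after irradiation. Filtering defaults off for dose reconstruction
    (it defaults on in the uniformity QA path).
    """
    from .densitometry import nod_map
    from .scan_io import FilmImage, average_scans, extract_red

    def as_maps(scans):
        return [extract_red(s) if isinstance(s, FilmImage) else s
                for s in scans]

    background = average_scans(as_maps(background_scans))
    exposed = average_scans(as_maps(exposed_scans))
    nod = nod_map(exposed, background)
    if apply_wiener:
        nod = wiener_filter(nod, wiener_window)
    return to_dose(nod, model, origin_mm=origin_mm)


def save_dose_map(path, dose_map: DoseMap) -> None:
    """32-bit float TIFF plus a JSON sidecar (spacing, origin, units)."""
    import json

    import tifffile

    tifffile.imwrite(path, dose_map.values.astype(np.float32),
                     compression=None)
    sidecar = {
        "units": "Gy",
        "pixel_spacing_mm": dose_map.pixel_spacing_mm,
        "origin_mm": list(dose_map.origin_mm),
        "n_clamped": dose_map.n_clamped,
        "n_out_of_range": dose_map.n_out_of_range,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_dose_map(path) -> DoseMap:
    import json

    import tifffile

    values = tifffile.imread(path).astype(float)
    with open(str(path) + ".json") as fh:
        sidecar = json.load(fh)
    return DoseMap(values=values,
                   pixel_spacing_mm=sidecar["pixel_spacing_mm"],
                   origin_mm=tuple(sidecar["origin_mm"]),
                   n_clamped=sidecar.get("n_clamped", 0),
                   n_out_of_range=sidecar.get("n_out_of_range", 0))
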