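"""Synthetic film scans, dose fields and scan series for pipeline testing.

Three generators stand in for the physical measurement chain:

* :func:`line_source_dose_field` — an analytic dose field around a
  two-pellet Co-60 line source in phantom (point-element superposition of
  an exponentially attenuated inverse-square kernel). It is ground truth
  for pipeline testing, deliberately simpler than a transport
  calculation: no anisotropy, scatter build-up or applicator shadowing.
* :func:`render_film` — the forward film/scanner model: dose -> NOD via
  the inverted calibration curve, NOD -> 16-bit pixels via the optical
  density relation, with controllable response-nonuniformity gain
  profiles, additive Gaussian pixel noise, per-scan OD drift, and
  optional quantization.
* :func:`make_qa_film_set` / :func:`drift_scan_series` — uniformly
  exposed QA film sets with injected nonuniformity (realized ground
  truths recorded alongside), and repeated-scan series of unexposed film
  for light-source sensitivity studies.

All randomness flows from the spec's seed; a fixed seed yields
byte-identical images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .calibration import CalibrationModel, ebt_reference_model
from .densitometry import nod_map
from .dose_reconstruction import DoseMap, to_dose
from .errors import DomainError, GeometryError, RangeError
from .scan_io import ROI, FilmImage, average_scans, extract_red
from .uniformity_qa import QA_ROI_CM

#: Green/blue channels respond weakly compared to red; rendered at this
#: fraction of the red-channel OD so channel-selection bugs are visible.
GB_OD_FRACTION = 0.2


# ---------------------------------------------------------------------------
# analytic source model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SourceModel:
    """Two-pellet Co-60 line source for the analytic dose kernel.

    The kernel of each point element is S * t * exp(-mu * r) / r^2 with r
    in cm, S the total strength in Gy cm^2 / s shared equally among the
    point elements, t the exposure time and mu an effective linear
    attenuation coefficient of the phantom medium.
    """

    strength_gy_cm2_per_s: float
    pellet_centers_mm: tuple[float, float] = (-3.0, 3.0)
    pellet_length_mm: float = 2.0
    pellet_diameter_mm: float = 1.0
    mu_eff_per_cm: float = 0.06
    exposure_time_s: float = 671.3

    def __post_init__(self) -> None:
        if self.strength_gy_cm2_per_s <= 0:
            raise DomainError("source strength must be positive")
        if self.mu_eff_per_cm < 0:
            raise DomainError("attenuation coefficient must be >= 0")
        if self.pellet_length_mm <= 0 or self.pellet_diameter_mm <= 0:
            raise DomainError("pellet geometry must be positive")

    def element_positions_mm(self, n_elements: int = 11) -> np.ndarray:
        """Axial positions of the point elements discretizing the pellets."""
        if n_elements < 10:
            raise DomainError("discretize each pellet into >= 10 elements")
        half = self.pellet_length_mm / 2.0
        return np.concatenate([
            np.linspace(c - half, c + half, n_elements)
            for c in self.pellet_centers_mm])

    @classmethod
    def calibrated(cls, dose_gy: float = 5.0,
                   at_mm: tuple[float, float] = (20.0, 20.0),
                   n_elements: int = 11, **kwargs) -> "SourceModel":
        """Source whose field delivers ``dose_gy`` at the point ``at_mm``
        (axial, lateral) over the exposure time — the usual prescription
        of a fixed dose at 2 cm axial / 2 cm lateral."""
        trial = cls(strength_gy_cm2_per_s=1.0, **kwargs)
        got = _point_dose(trial, np.array([at_mm[0]]), np.array([at_mm[1]]),
                          n_elements)[0]
        return replace(trial, strength_gy_cm2_per_s=float(dose_gy / got))


def _point_dose(source: SourceModel, x_mm: np.ndarray, y_mm: np.ndarray,
                n_elements: int) -> np.ndarray:
    elems = source.element_positions_mm(n_elements)
    per_element = (source.strength_gy_cm2_per_s * source.exposure_time_s
                   / elems.size)
    dose = np.zeros(np.broadcast(x_mm, y_mm).shape)
    for xe in elems:
        r_cm = np.hypot(x_mm - xe, y_mm) / 10.0
        dose += per_element * np.exp(-source.mu_eff_per_cm * r_cm) / r_cm ** 2
    return dose


def line_source_dose_field(source: SourceModel,
                           extent_mm: tuple[tuple[float, float],
                                            tuple[float, float]],
                           spacing_mm: float,
                           n_elements: int = 11) -> DoseMap:
    """Analytic dose field on a regular grid in the film plane.

    ``extent_mm`` is ((x0, x1), (y0, y1)) with x the longitudinal (source
    axis) coordinate and y the transverse distance from the axis; pixel
    centers start half a spacing inside the extent. Every grid point must
    be at least half a pixel away from every source element.
    """
    (x0, x1), (y0, y1) = extent_mm
    if spacing_mm <= 0 or x1 <= x0 or y1 <= y0:
        raise GeometryError("invalid grid specification")
    nx = int(round((x1 - x0) / spacing_mm))
    ny = int(round((y1 - y0) / spacing_mm))
    x = x0 + (np.arange(nx) + 0.5) * spacing_mm
    y = y0 + (np.arange(ny) + 0.5) * spacing_mm
    xx, yy = np.meshgrid(x, y, indexing="ij")
    elems = source.element_positions_mm(n_elements)
    min_r = min(float(np.hypot(xx - xe, yy).min()) for xe in elems)
    if min_r < spacing_mm / 2.0:
        raise GeometryError(
            f"grid approaches the source axis (min distance {min_r:.3g} mm "
            f"< half pixel {spacing_mm / 2:.3g} mm)")
    dose = _point_dose(source, xx, yy, n_elements)
    return DoseMap(values=dose, pixel_spacing_mm=spacing_mm,
                   origin_mm=(x0, y0))


# ---------------------------------------------------------------------------
# forward film/scanner model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilmRenderSpec:
    """Everything the forward scanner model needs besides the dose.

    ``longitudinal_gain_pp`` / ``transverse_gain_pp`` are peak-to-peak
    fractions of smooth multiplicative OD response profiles (half-period
    sine, unity at the film center). ``per_scan_delta_od`` is the OD added
    by each successive scan of a series (light-source darkening).
    ``quantize=False`` keeps continuous pixel values, isolating the
    analytic chain from 16-bit quantization in round-trip checks.
    """

    calibration: CalibrationModel = field(default_factory=ebt_reference_model)
    background_od: float = 0.10
    white_level: float = 65535.0
    pixel_noise_sigma: float = 0.0
    longitudinal_gain_pp: float = 0.0
    transverse_gain_pp: float = 0.0
    per_scan_delta_od: float = 0.0
    seed: int = 0
    quantize: bool = True

    def __post_init__(self) -> None:
        if self.background_od < 0:
            raise DomainError("background OD must be >= 0")
        if self.white_level <= 0:
            raise DomainError("white level must be positive")
        if self.pixel_noise_sigma < 0:
            raise DomainError("noise sigma must be >= 0")


@dataclass
class RenderedFilm:
    """A rendered film: background and exposed scan series plus truth."""

    background: list[FilmImage]
    exposed: list[FilmImage]
    dose: DoseMap
    spec: FilmRenderSpec

    def averaged_pair(self):
        """(background, exposed) red-channel maps, scans averaged."""
        bg = average_scans([extract_red(s) for s in self.background])
        exp = average_scans([extract_red(s) for s in self.exposed])
        return bg, exp


def _gain_profile(n: int, peak_to_peak: float) -> np.ndarray:
    """Smooth multiplicative profile: 1 + (pp/2) sin(2 pi t), t in [0, 1].

    Unity at the film center, extremes at the quarter positions, so the
    observed peak-to-peak of the collapsed profile equals ``peak_to_peak``
    exactly even after central-ROI cropping.
    """
    t = np.arange(n) / (n - 1)
    return 1.0 + (peak_to_peak / 2.0) * np.sin(2.0 * np.pi * t)


def _gain_field(shape: tuple[int, int], spec: FilmRenderSpec) -> np.ndarray:
    long_profile = _gain_profile(shape[0], spec.longitudinal_gain_pp)
    trans_profile = _gain_profile(shape[1], spec.transverse_gain_pp)
    return np.outer(long_profile, trans_profile)


def _od_to_image(od: np.ndarray, spec: FilmRenderSpec,
                 rng: np.random.Generator, dpi: float) -> FilmImage:
    pixels = np.empty(od.shape + (3,), dtype=float)
    pixels[:, :, 0] = spec.white_level * 10.0 ** (-od)
    gb = spec.white_level * 10.0 ** (-GB_OD_FRACTION * od)
    pixels[:, :, 1] = gb
    pixels[:, :, 2] = gb
    if spec.pixel_noise_sigma > 0:
        pixels += rng.normal(0.0, spec.pixel_noise_sigma, size=pixels.shape)
    pixels = np.clip(pixels, 1.0, 65535.0)
    if spec.quantize:
        pixels = np.rint(pixels).astype(np.uint16)
    return FilmImage(pixels=pixels, dpi=dpi)


def film_od_maps(dose: DoseMap, spec: FilmRenderSpec) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless (background, exposed) total-OD maps for a dose field.

    Doses below the calibration curve's minimum representable dose render
    as background (zero NOD); doses above its maximum raise
    :class:`~filmdose.errors.RangeError`.
    """
    model = spec.calibration
    dmin, dmax = model.dose_range_gy
    values = dose.values
    if float(values.max()) > dmax:
        raise RangeError(
            f"dose {values.max():.4g} Gy above representable maximum",
            dose_min=dmin, dose_max=dmax)
    nod = np.zeros_like(values)
    in_range = values >= dmin
    if in_range.any():
        nod[in_range] = model.invert(values[in_range])
    gain = _gain_field(values.shape, spec)
    return spec.background_od * gain, (spec.background_od + nod) * gain


def render_film(dose: DoseMap, spec: FilmRenderSpec,
                n_scans: int = 1) -> RenderedFilm:
    """Render a dose field as background and exposed scan series.

    Scan k (1-based) of each series carries an extra (k-1) *
    ``per_scan_delta_od`` of drift, emulating cumulative darkening by the
    scanner's light source within that scanning session.
    """
    if n_scans < 1:
        raise DomainError("n_scans must be >= 1")
    od_back, od_exp = film_od_maps(dose, spec)
    rng = np.random.default_rng(spec.seed)
    dpi = 25.4 / dose.pixel_spacing_mm
    background = [
        _od_to_image(od_back + k * spec.per_scan_delta_od, spec, rng, dpi)
        for k in range(n_scans)]
    exposed = [
        _od_to_image(od_exp + k * spec.per_scan_delta_od, spec, rng, dpi)
        for k in range(n_scans)]
    return RenderedFilm(background=background, exposed=exposed,
                        dose=dose, spec=spec)


# ---------------------------------------------------------------------------
# QA film sets and scan series
# ---------------------------------------------------------------------------

@dataclass
class QAFilm:
    """One uniformly exposed QA film with its realized ground truths."""

    rendered: RenderedFilm
    true_cv_percent: float
    true_delta_od_longitudinal_percent: float
    true_delta_od_transverse_percent: float
    roi: ROI


def _smooth_cv_field(shape: tuple[int, int], roi: ROI, cv: float,
                     rng: np.random.Generator,
                     correlation_px: float = 12.0) -> np.ndarray:
    """Smooth multiplicative nonuniformity field with exact dose-domain CV
    over the ROI.

    The field is low-pass Gaussian noise, doubly centered over the ROI
    (row and column means removed) so that it is orthogonal to the
    direction-collapsed profiles used by the peak-to-peak statistic, then
    scaled to the requested coefficient of variation.
    """
    g = gaussian_filter(rng.standard_normal(shape), correlation_px,
                        mode="reflect")
    sub = g[roi.row_start:roi.row_stop, roi.col_start:roi.col_stop]
    centered = (sub - sub.mean(axis=1, keepdims=True)
                - sub.mean(axis=0, keepdims=True) + sub.mean())
    g[roi.row_start:roi.row_stop, roi.col_start:roi.col_stop] = centered
    scale = centered.std()
    if scale == 0:
        return np.ones(shape)
    return 1.0 + cv * (g - sub.mean()) / scale


def _realized_truth(dose_field: np.ndarray, spacing_mm: float,
                    spec: FilmRenderSpec, roi: ROI):
    """Ground-truth statistics of the noiseless rendered film.

    Evaluated on the ideal (noise- and quantization-free) OD and dose
    maps the pipeline would see, so cross-coupling of the OD gain
    profiles into dose CV is part of the recorded truth.
    """
    from .densitometry import NODMap
    from .uniformity_qa import (LONGITUDINAL, TRANSVERSE, cv_percent,
                                delta_od_peak)

    dmap = DoseMap(values=dose_field, pixel_spacing_mm=spacing_mm)
    od_back, od_exp = film_od_maps(dmap, spec)
    nod = NODMap(values=od_exp - od_back, pixel_spacing_mm=spacing_mm)
    recovered = to_dose(nod, spec.calibration)
    od = NODMap(values=od_exp, pixel_spacing_mm=spacing_mm)
    return (cv_percent(recovered, roi),
            delta_od_peak(od, LONGITUDINAL, roi),
            delta_od_peak(od, TRANSVERSE, roi))


def make_qa_film_set(n_films: int,
                     spec: FilmRenderSpec | None = None,
                     nominal_dose_gy: float = 10.0,
                     injected_cv: float = 0.0,
                     injected_longitudinal_pp: float = 0.0,
                     injected_transverse_pp: float = 0.0,
                     film_size_cm: tuple[float, float] = (20.3, 12.7),
                     dpi: float = 100.0,
                     roi_size_cm: tuple[float, float] = QA_ROI_CM,
                     n_scans: int = 3) -> list[QAFilm]:
    """Uniformly exposed QA films with controllable nonuniformity.

    ``injected_cv`` is the dose-domain coefficient of variation of a
    smooth spatial nonuniformity field (fraction, e.g. 0.03);
    ``injected_*_pp`` are OD peak-to-peak fractions of the directional
    gain profiles. Realized ground truths (including the coupling of OD
    profiles into dose CV) are recorded on each :class:`QAFilm`.
    """
    if n_films < 1:
        raise DomainError("n_films must be >= 1")
    if spec is None:
        spec = FilmRenderSpec()
    spacing = 25.4 / dpi
    shape = (round(film_size_cm[0] * 10 / spacing),
             round(film_size_cm[1] * 10 / spacing))
    roi = ROI.centered_cm(shape, spacing, roi_size_cm)
    films: list[QAFilm] = []
    for i in range(n_films):
        film_seed = (spec.seed + 7919 * i) % (2 ** 31)
        film_spec = replace(spec, seed=film_seed,
                            longitudinal_gain_pp=injected_longitudinal_pp,
                            transverse_gain_pp=injected_transverse_pp)
        rng = np.random.default_rng((film_seed + 104729) % (2 ** 31))
        field_values = np.full(shape, float(nominal_dose_gy))
        if injected_cv > 0:
            field_values = field_values * _smooth_cv_field(
                shape, roi, injected_cv, rng)
        dose = DoseMap(values=field_values, pixel_spacing_mm=spacing)
        truth = _realized_truth(field_values, spacing, film_spec, roi)
        films.append(QAFilm(
            rendered=render_film(dose, film_spec, n_scans=n_scans),
            true_cv_percent=truth[0],
            true_delta_od_longitudinal_percent=truth[1],
            true_delta_od_transverse_percent=truth[2],
            roi=roi))
    return films


def drift_scan_series(spec: FilmRenderSpec, n_scans: int = 15,
                      film_size_cm: tuple[float, float] = (20.3, 12.7),
                      dpi: float = 100.0) -> list[FilmImage]:
    """Repeated scans of one unexposed film with per-scan OD drift.

    Emulates the light-source sensitivity protocol: the same film scanned
    ``n_scans`` times, each scan adding ``spec.per_scan_delta_od`` to its
    optical density.
    """
    if n_scans < 2:
        raise DomainError("a drift series needs >= 2 scans")
    spacing = 25.4 / dpi
    shape = (round(film_size_cm[0] * 10 / spacing),
             round(film_size_cm[1] * 10 / spacing))
    zero = DoseMap(values=np.zeros(shape), pixel_spacing_mm=spacing)
    rendered = render_film(zero, spec, n_scans=n_scans)
    return rendered.background
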