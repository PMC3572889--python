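"""Film + scanner response uniformity statistics.

Two ratio statistics quantify the combined nonuniformity of film batch
and scanner over a region of interest of a nominally uniformly exposed
film:

* the coefficient of variation of the reconstructed dose,
  CV = 100 * sigma / mu (population sigma), and
* the peak-to-peak optical-density variation per direction,
  dOD_peak = 100 * (OD_max - OD_min) / OD_central,
  evaluated on the 1-D mean OD profile obtained by collapsing the ROI
  along the orthogonal axis ("central" = middle index of the profile,
  left of center for even lengths).

CV lives in the dose domain and dOD_peak in the OD domain. Both are by
default computed on Wiener-filtered maps, mirroring the QA protocol of
filtering scans before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .calibration import CalibrationModel
from .densitometry import NODMap, nod_map
from .dose_reconstruction import DoseMap, to_dose, wiener_filter
from .errors import DomainError
from .scan_io import ROI, ChannelMap, crop_roi

#: Standard QA region of interest: central 16 cm x 11 cm of the film.
QA_ROI_CM = (16.0, 11.0)

LONGITUDINAL = "longitudinal"
TRANSVERSE = "transverse"


@dataclass(frozen=True)
class UniformityReport:
    """Per-film uniformity statistics over one ROI."""

    cv_percent: float
    delta_od_peak_longitudinal_percent: float
    delta_od_peak_transverse_percent: float
    roi: ROI

    def __post_init__(self) -> None:
        if (self.cv_percent < 0
                or self.delta_od_peak_longitudinal_percent < 0
                or self.delta_od_peak_transverse_percent < 0):
            raise DomainError("uniformity statistics must be non-negative")


@dataclass(frozen=True)
class UniformitySummary:
    """Aggregate over a film set: unweighted means plus min-max ranges."""

    reports: tuple[UniformityReport, ...]
    mean_cv_percent: float
    cv_range_percent: tuple[float, float]
    mean_delta_od_longitudinal_percent: float
    delta_od_longitudinal_range_percent: tuple[float, float]
    mean_delta_od_transverse_percent: float
    delta_od_transverse_range_percent: tuple[float, float]


def _roi_values(data, roi: ROI | None) -> np.ndarray:
    values = data.values if hasattr(data, "values") else np.asarray(data, float)
    if roi is None:
        return values
    roi.validate(values.shape)
    return values[roi.row_start:roi.row_stop, roi.col_start:roi.col_stop]


def cv_percent(data, roi: ROI | None = None) -> float:
    """Coefficient of variation, 100*sigma/mu, over the ROI pixels.

    ``data`` may be a DoseMap, NODMap, ChannelMap or bare 2-D array.
    Population (divide-by-N) standard deviation.
    """
    values = _roi_values(data, roi)
    mu = float(values.mean())
    if mu <= 0:
        raise DomainError(f"CV undefined for non-positive ROI mean {mu}")
    return 100.0 * float(values.std()) / mu


def delta_od_peak(od_data, direction: str, roi: ROI | None = None) -> float:
    """Peak-to-peak variation of the direction-collapsed mean OD profile.

    ``direction`` 'longitudinal' collapses over the transverse axis and
    profiles along the first array index; 'transverse' the converse.
    Returns 100 * (max - min) / central-index value.
    """
    values = _roi_values(od_data, roi)
    if direction == LONGITUDINAL:
        profile = values.mean(axis=1)
    elif direction == TRANSVERSE:
        profile = values.mean(axis=0)
    else:
        raise ValueError(
            f"direction must be '{LONGITUDINAL}' or '{TRANSVERSE}', "
            f"got {direction!r}")
    central = float(profile[(len(profile) - 1) // 2])
    if central <= 0:
        raise DomainError(f"non-positive central profile value {central}")
    return 100.0 * float(profile.max() - profile.min()) / central


def film_uniformity(background: ChannelMap, exposed: ChannelMap,
                    model: CalibrationModel,
                    roi: ROI | None = None,
                    roi_size_cm: tuple[float, float] = QA_ROI_CM,
                    apply_wiener: bool = True,
                    wiener_window: int = 5,
                    white_reference: float = 65535.0) -> UniformityReport:
    """Uniformity statistics for one film from its scan pair.

    Pipeline: NOD from the background/exposed pair, absolute OD of the
    exposed scan, optional 5x5 Wiener filtering of both, calibration to
    dose for CV, directional profile statistics on the OD map.
    """
    if roi is None:
        roi = ROI.centered_cm(exposed.shape, exposed.pixel_spacing_mm,
                              roi_size_cm)
    nod = nod_map(exposed, background)
    od = NODMap(values=np.log10(white_reference / exposed.values),
                pixel_spacing_mm=exposed.pixel_spacing_mm)
    dose = to_dose(nod, model)
    if apply_wiener:
        dose = wiener_filter(dose, wiener_window)
        od = wiener_filter(od, wiener_window)
    return UniformityReport(
        cv_percent=cv_percent(dose, roi),
        delta_od_peak_longitudinal_percent=delta_od_peak(od, LONGITUDINAL, roi),
        delta_od_peak_transverse_percent=delta_od_peak(od, TRANSVERSE, roi),
        roi=roi)


def uniformity_report(film_pairs: Sequence[tuple[ChannelMap, ChannelMap]],
                      model: CalibrationModel,
                      **kwargs) -> UniformitySummary:
    """Per-film statistics plus unweighted means and min-max ranges.

    ``film_pairs`` is a list of (background scan, exposed scan) red-channel
    maps, one pair per QA film; keyword arguments pass to
    :func:`film_uniformity`.
    """
    if len(film_pairs) == 0:
        raise DomainError("need at least one film pair")
    reports = tuple(film_uniformity(bg, exp, model, **kwargs)
                    for bg, exp in film_pairs)
    cvs = np.array([r.cv_percent for r in reports])
    dl = np.array([r.delta_od_peak_longitudinal_percent for r in reports])
    dt = np.array([r.delta_od_peak_transverse_percent for r in reports])
    return UniformitySummary(
        reports=reports,
        mean_cv_percent=float(cvs.mean()),
        cv_range_percent=(float(cvs.min()), float(cvs.max())),
        mean_delta_od_longitudinal_percent=float(dl.mean()),
        delta_od_longitudinal_range_percent=(float(dl.min()), float(dl.max())),
        mean_delta_od_transverse_percent=float(dt.mean()),
        delta_od_transverse_range_percent=(float(dt.min()), float(dt.max())))
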