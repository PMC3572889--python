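"""Optical density and net optical density from scanner pixel values.

Net optical density (NOD) is the dose-bearing signal of a radiochromic
film: the base-10 optical density of the exposed film minus the optical
density of the same film before exposure,

    NOD = OD_cal - OD_back = -(log10(P_cal) - log10(P_back)),

where P_cal and P_back are red-channel pixel values of the exposed and
background scans. NOD depends only on the pixel ratio, so no white
reference enters; absolute OD (``mean_od``) does need one and defaults to
the 16-bit full-transmission value 65535.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DimensionError, DomainError, FormatError
from .scan_io import ChannelMap

WHITE_16BIT = 65535.0


@dataclass
class NODMap:
    """Per-pixel net optical density (dimensionless, base 10)."""

    values: np.ndarray
    pixel_spacing_mm: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("NOD map must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise DomainError("NOD map contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class DriftReport:
    """Optical-density drift accumulated over a repeated-scan series."""

    total_delta_od: float
    n_scans: int
    per_scan_delta_od: float

    def __post_init__(self) -> None:
        if self.n_scans < 2:
            raise DomainError("drift needs at least 2 scans")


def _check_positive(values: np.ndarray, name: str) -> None:
    bad = values <= 0
    if np.any(bad):
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise DomainError(
            f"{name} has non-positive pixel value {values[idx]} at {idx}")


def nod_map(p_cal: ChannelMap, p_back: ChannelMap) -> NODMap:
    """Net optical density map from exposed and background scans.

    Both maps must share shape and spacing; every pixel must be positive
    (a zero pixel has no defined optical density).
    """
    if p_cal.shape != p_back.shape:
        raise DimensionError(
            f"shapes disagree: exposed {p_cal.shape} vs background {p_back.shape}")
    _check_positive(p_cal.values, "exposed scan")
    _check_positive(p_back.values, "background scan")
    values = np.log10(p_back.values) - np.log10(p_cal.values)
    return NODMap(values=values, pixel_spacing_mm=p_cal.pixel_spacing_mm)


def mean_od(cmap: ChannelMap, white_reference: float = WHITE_16BIT) -> float:
    """Mean absolute optical density of one film piece.

    OD = log10(white_reference / mean pixel value); the mean is taken over
    the whole map (crop the film edges first if desired).
    """
    if white_reference <= 0:
        raise DomainError("white reference must be positive")
    _check_positive(cmap.values, "scan")
    mean_pixel = float(cmap.values.mean())
    return float(np.log10(white_reference / mean_pixel))


def drift_per_scan(od_series: Sequence[float],
                   n_scans: int | None = None) -> DriftReport:
    """Per-scan optical-density drift of a film scanned repeatedly.

    ``od_series`` is an ordered series of mean-OD readings of the same
    film. The total change is last minus first; the per-scan change
    divides the total by the number of scans ``n_scans`` (default: the
    series length). Passing ``n_scans`` explicitly supports the common
    before/after protocol where only two readings bracket a longer run
    of scans.
    """
    series = [float(v) for v in od_series]
    if len(series) < 2:
        raise DomainError("drift series needs at least 2 readings")
    if n_scans is None:
        n_scans = len(series)
    if n_scans < 2:
        raise DomainError("n_scans must be at least 2")
    total = series[-1] - series[0]
    return DriftReport(total_delta_od=total, n_scans=n_scans,
                       per_scan_delta_od=total / n_scans)


def pooled_drift(series_list: Sequence[Sequence[float]],
                 n_scans: int | None = None) -> DriftReport:
    """Drift averaged over several films (unweighted mean of totals)."""
    if len(series_list) == 0:
        raise DomainError("need at least one drift series")
    reports = [drift_per_scan(s, n_scans=n_scans) for s in series_list]
    ns = {r.n_scans for r in reports}
    if len(ns) != 1:
        raise DimensionError(f"scan counts disagree across films: {sorted(ns)}")
    n = ns.pop()
    total = float(np.mean([r.total_delta_od for r in reports]))
    return DriftReport(total_delta_od=total, n_scans=n,
                       per_scan_delta_od=total / n)
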