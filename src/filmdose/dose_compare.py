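"""Isodose-level comparison between independently produced dose maps.

The comparison metric: extract each requested isodose contour from the
*reference* map, sample the *other* map by bilinear interpolation at every
contour vertex (in shared physical coordinates), and report per level the
mean and maximum of 100 * |D_other(vertex) - L| / L. The overall figure is
the unweighted mean over reported levels, by default excluding the lowest
(1.25 Gy) rung of the standard ladder, where scanner noise dominates.

Maps may live on different grids; the comparison happens purely in
physical mm coordinates and never resamples the reference map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .dose_reconstruction import DoseMap, extract_isodose
from .errors import GeometryError

#: Standard isodose ladder, Gy.
DEFAULT_LEVELS = (1.25, 2.5, 3.75, 5.0, 6.25, 7.5)
#: Levels excluded from the overall aggregate by default.
DEFAULT_EXCLUDE_FROM_OVERALL = (1.25,)


@dataclass(frozen=True)
class LevelComparison:
    level_gy: float
    mean_percent_diff: float | None
    max_percent_diff: float | None
    n_samples: int
    n_dropped: int = 0

    @property
    def present(self) -> bool:
        return self.n_samples >= 1


@dataclass(frozen=True)
class ComparisonReport:
    """Per-level and overall percent dose differences between two maps."""

    per_level: tuple[LevelComparison, ...]
    overall_mean_percent_diff: float | None
    reference_name: str = "reference"
    other_name: str = "other"

    def level(self, level_gy: float) -> LevelComparison:
        for lc in self.per_level:
            if np.isclose(lc.level_gy, level_gy):
                return lc
        raise KeyError(f"level {level_gy} Gy not in report")

    def to_dict(self) -> dict:
        return {
            "reference": self.reference_name,
            "other": self.other_name,
            "overall_mean_percent_diff": self.overall_mean_percent_diff,
            "per_level": [
                {"level_gy": lc.level_gy,
                 "mean_percent_diff": lc.mean_percent_diff,
                 "max_percent_diff": lc.max_percent_diff,
                 "n_samples": lc.n_samples,
                 "n_dropped": lc.n_dropped}
                for lc in self.per_level],
        }


def _interpolator(dose_map: DoseMap) -> RegularGridInterpolator:
    rows, cols = dose_map.axes_mm()
    return RegularGridInterpolator((rows, cols), dose_map.values,
                                   method="linear", bounds_error=False,
                                   fill_value=np.nan)


def _overlap(a: DoseMap, b: DoseMap) -> bool:
    (ar, ac), (br, bc) = a.axes_mm(), b.axes_mm()
    return (max(ar[0], br[0]) < min(ar[-1], br[-1])
            and max(ac[0], bc[0]) < min(ac[-1], bc[-1]))


def compare_isodose(reference: DoseMap, other: DoseMap,
                    levels: Sequence[float] = DEFAULT_LEVELS,
                    exclude_from_overall: Sequence[float] = DEFAULT_EXCLUDE_FROM_OVERALL,
                    reference_name: str = "reference",
                    other_name: str = "other") -> ComparisonReport:
    """Percent dose difference sampled along reference isodose lines.

    For each level the reference map's contours are extracted; the other
    map is interpolated bilinearly at each contour vertex; vertices
    falling outside the other map's extent are dropped and counted. A
    level with no reference contour (or no surviving vertices) is marked
    absent rather than erroring.
    """
    if not _overlap(reference, other):
        raise GeometryError("dose maps share no physical region")
    interp = _interpolator(other)
    per_level: list[LevelComparison] = []
    for level in levels:
        contours = extract_isodose(reference, [level])
        if not contours:
            per_level.append(LevelComparison(level, None, None, 0))
            continue
        vertices = np.vstack([c.vertices for c in contours])
        sampled = interp(vertices)
        ok = np.isfinite(sampled)
        n_dropped = int((~ok).sum())
        if not ok.any():
            per_level.append(LevelComparison(level, None, None, 0, n_dropped))
            continue
        diffs = 100.0 * np.abs(sampled[ok] - level) / level
        per_level.append(LevelComparison(
            level_gy=float(level),
            mean_percent_diff=float(diffs.mean()),
            max_percent_diff=float(diffs.max()),
            n_samples=int(ok.sum()),
            n_dropped=n_dropped))
    aggregate = [lc.mean_percent_diff for lc in per_level
                 if lc.present and not any(np.isclose(lc.level_gy, e)
                                           for e in exclude_from_overall)]
    overall = float(np.mean(aggregate)) if aggregate else None
    return ComparisonReport(per_level=tuple(per_level),
                            overall_mean_percent_diff=overall,
                            reference_name=reference_name,
                            other_name=other_name)


def comparison_table(pairs: Mapping[str, ComparisonReport]) -> pd.DataFrame:
    """Summary table: one row per comparison pair.

    Columns: the overall mean percent difference plus one column per
    isodose level present in any report.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one comparison report")
    levels = sorted({lc.level_gy for r in pairs.values() for lc in r.per_level})
    rows = {}
    for name, report in pairs.items():
        row = {"overall_%": report.overall_mean_percent_diff}
        for level in levels:
            try:
                lc = report.level(level)
                row[f"{level:g} Gy %"] = lc.mean_percent_diff
            except KeyError:
                row[f"{level:g} Gy %"] = None
        rows[name] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def format_table(table: pd.DataFrame) -> str:
    """Aligned-text rendering of a comparison table."""
    return table.to_string(float_format=lambda v: f"{v:.2f}",
                           na_rep="absent")
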