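"""Turn raw combined series into agar-subtracted, QC-flagged growth curves.

The colony signal is A = raw − agar, subtracted per well from the pre-print
blank.  Negative corrected values (possible in the first-hour bubble dip or
on noisy blanks) are kept and flagged rather than clipped, so printed-mass
and lag estimates stay unbiased.  Saturated wells (any raw reading at the
3.5 reader ceiling) are flagged but retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .plate_core import (ExperimentSeries, PlatePhenError, SATURATION_CEILING)


class PreprocessError(PlatePhenError):
    pass


FLAG_SATURATED = "saturated"
FLAG_NEGATIVE = "negative_corrected"
FLAG_EMPTY = "empty"


@dataclass
class ProcessedSeries:
    """Agar-subtracted series with per-well QC flags.

    corrected = raw − agar elementwise; printed_mass is the corrected value
    at the earliest post-print timepoint (the inoculum-size proxy); flags is
    a boolean DataFrame indexed by well label with columns saturated /
    negative_corrected / empty.
    """

    base: ExperimentSeries
    corrected: np.ndarray     # (timepoints, wells)
    printed_mass: np.ndarray  # (wells,)
    flags: pd.DataFrame

    @property
    def times_s(self) -> np.ndarray:
        return self.base.times_s

    @property
    def labels(self) -> list[str]:
        return self.base.geometry.labels()

    def curve(self, label: str) -> np.ndarray:
        return self.corrected[:, self.base.geometry.label_index(label)]


def subtract_agar(series: ExperimentSeries) -> ProcessedSeries:
    """Subtract the per-well agar reference from every timepoint."""
    if np.any(~np.isfinite(series.agar)):
        bad = [series.geometry.labels()[i]
               for i in np.flatnonzero(~np.isfinite(series.agar))]
        raise PreprocessError(f"missing agar reference for wells {bad[:5]}")
    corrected = series.series - series.agar[None, :]
    printed_mass = corrected[0, :].copy()
    labels = series.geometry.labels()
    flags = pd.DataFrame(False, index=pd.Index(labels, name="position"),
                         columns=[FLAG_SATURATED, FLAG_NEGATIVE, FLAG_EMPTY])
    with np.errstate(invalid="ignore"):
        flags[FLAG_SATURATED] = np.nanmax(series.series, axis=0) >= SATURATION_CEILING
        flags[FLAG_NEGATIVE] = np.nanmin(corrected, axis=0) < 0
    if series.layout is not None:
        empty = [series.layout.strain_at(lab) == "" for lab in labels]
        flags[FLAG_EMPTY] = empty
    return ProcessedSeries(series, corrected, printed_mass, flags)


def snapshot_clusters(times_s: np.ndarray,
                      gap_threshold_s: float | None = None) -> list[np.ndarray]:
    """Group timepoints into rapid-succession pass clusters.

    A new cluster starts wherever the gap to the previous timepoint exceeds
    the threshold (default: 3× the median spacing), separating snapshot
    passes from the long waits between plate visits.
    """
    times_s = np.asarray(times_s, dtype=float)
    if len(times_s) == 0:
        return []
    if len(times_s) == 1:
        return [np.array([0])]
    gaps = np.diff(times_s)
    if gap_threshold_s is None:
        gap_threshold_s = 3.0 * float(np.median(gaps))
    breaks = np.flatnonzero(gaps > gap_threshold_s) + 1
    return [np.asarray(idx) for idx in np.split(np.arange(len(times_s)), breaks)]


def snapshot_average(times_s: np.ndarray, values: np.ndarray,
                     gap_threshold_s: float | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Average each pass cluster to a single timepoint.

    Successive passes of a snapshot protocol are averaged to tame the
    measurement variance seen at high absorbance; the cluster time is the
    mean of member times.  ``values`` may be (T,) or (T, wells).
    """
    values = np.asarray(values, dtype=float)
    clusters = snapshot_clusters(times_s, gap_threshold_s)
    out_t = np.array([np.mean(np.asarray(times_s, float)[idx]) for idx in clusters])
    out_v = np.array([np.nanmean(values[idx], axis=0) for idx in clusters])
    return out_t, out_v


def normalize_to_minimum(curve: np.ndarray) -> np.ndarray:
    """Shift a curve so its minimum is zero (aligns curves despite early dips)."""
    curve = np.asarray(curve, dtype=float)
    if not np.any(np.isfinite(curve)):
        raise PreprocessError("cannot normalize an all-missing curve")
    return curve - np.nanmin(curve)


def moving_average_smooth(curve: np.ndarray, window_points: int) -> np.ndarray:
    """Centered moving mean with truncated windows at the endpoints."""
    if window_points < 1 or window_points % 2 == 0:
        raise PreprocessError(f"smoothing window must be odd and >= 1, "
                              f"got {window_points}")
    s = pd.Series(np.asarray(curve, dtype=float))
    return s.rolling(window_points, center=True, min_periods=1).mean().to_numpy()


def variance_profile(items: np.ndarray | list) -> tuple[pd.DataFrame, float, float]:
    """Per-item mean and sample SD of successive readings, plus the SD-on-mean trend.

    Measurement noise on this instrument grows with overall absorbance, so
    the OLS line SD = intercept + slope·mean summarises the noise model.
    Returns (table, slope, intercept).
    """
    rows = []
    for k, readings in enumerate(items):
        arr = np.asarray(readings, dtype=float)
        arr = arr[np.isfinite(arr)]
        if len(arr) < 2:
            raise PreprocessError(f"item {k}: need >= 2 successive readings")
        rows.append({"item": k, "mean": float(arr.mean()),
                     "sd": float(arr.std(ddof=1))})
    table = pd.DataFrame(rows)
    if len(table) >= 2 and table["mean"].nunique() > 1:
        fit = stats.linregress(table["mean"], table["sd"])
        slope, intercept = float(fit.slope), float(fit.intercept)
    else:
        slope, intercept = 0.0, float(table["sd"].mean())
    return table, slope, intercept


def edge_effect_ratio(proc: ProcessedSeries, time_s: float) -> float:
    """Perimeter / interior mean corrected absorbance at the nearest timepoint.

    Nutrient availability lets perimeter colonies keep growing late (after
    ~40 h on rich media); 1.0 indicates no edge effect.  Empty wells are
    excluded.
    """
    geometry = proc.base.geometry
    if geometry.n_rows < 3 or geometry.n_cols < 3:
        raise PreprocessError("no interior wells at this geometry")
    t_idx = int(np.argmin(np.abs(proc.times_s - time_s)))
    rows, cols = np.divmod(np.arange(geometry.n_wells), geometry.n_cols)
    perimeter = ((rows == 0) | (rows == geometry.n_rows - 1) |
                 (cols == 0) | (cols == geometry.n_cols - 1))
    occupied = ~proc.flags[FLAG_EMPTY].to_numpy()
    values = proc.corrected[t_idx, :]
    per = values[perimeter & occupied]
    inner = values[~perimeter & occupied]
    if len(inner) == 0 or len(per) == 0:
        raise PreprocessError("need occupied perimeter and interior wells")
    return float(np.nanmean(per) / np.nanmean(inner))
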