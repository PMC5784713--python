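"""Named phenotype calculators: one summary value per colony per calculator.

Each calculator maps a processed growth curve (or a treatment/control pair)
to a single number.  Calculators live in a registry keyed by their camel-case
names so new ones can be added without touching the runner; the windowed
calculators (AverageWithoutAgarCalc, TreatmentRatioCalc) require an explicit
time window, since averaging within a window is the standard remedy for the
measurement variance seen at high absorbance.

Registered calculators
----------------------
- ``AverageWithoutAgarCalc``  mean corrected absorbance within a window
- ``MaximumWithoutAgarCalc``  maximum corrected absorbance
- ``MaxChangeCalc``           max rise over the first reading
- ``MaxSlopeCalc``            steepest sliding-window OLS slope (per hour),
  with the inflection time and a multiphasic warning
- ``LagCalc``                 time to exceed printed mass by a set fraction
  of the rise to plateau
- ``TreatmentRatioCalc``      windowed average under treatment / control
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .plate_core import PlatePhenError
from .preprocess import (FLAG_EMPTY, ProcessedSeries, moving_average_smooth)


class CalculatorError(PlatePhenError):
    pass


class UndefinedValueError(CalculatorError):
    """The calculator's value is undefined for this curve; carries the reason."""


class ConfigError(PlatePhenError):
    pass


DEFAULT_SLOPE_WINDOW_POINTS = 5   # 100 min at 20-min reading intervals
DEFAULT_SMOOTH_WINDOW = 3
DEFAULT_LAG_FRACTION = 0.05
DEFAULT_EPSILON = 0.05            # minimum control absorbance for a ratio
MULTIPHASIC_WARN_FRACTION = 0.8


# ---------------------------------------------------------------------------
# Individual calculators
# ---------------------------------------------------------------------------

def average_without_agar(times_s, curve, window_s) -> float:
    """Mean corrected absorbance over the closed time window [t0, t1]."""
    times_s = np.asarray(times_s, float)
    curve = np.asarray(curve, float)
    t0, t1 = window_s
    mask = (times_s >= t0) & (times_s <= t1) & np.isfinite(curve)
    if not mask.any():
        raise UndefinedValueError(f"no timepoints in window [{t0}, {t1}] s")
    return float(curve[mask].mean())


def maximum_without_agar(times_s, curve) -> float:
    curve = np.asarray(curve, float)
    if not np.any(np.isfinite(curve)):
        raise UndefinedValueError("all readings missing")
    return float(np.nanmax(curve))


def max_change(times_s, curve) -> float:
    """Largest rise above the first reading, wherever it occurs."""
    curve = np.asarray(curve, float)
    finite = np.flatnonzero(np.isfinite(curve))
    if len(finite) < 2:
        raise UndefinedValueError("need >= 2 readings")
    first = curve[finite[0]]
    return float(np.nanmax(curve) - first)


def max_slope(times_s, curve, smooth_window: int = DEFAULT_SMOOTH_WINDOW,
              window_points: int = DEFAULT_SLOPE_WINDOW_POINTS
              ) -> tuple[float, float, bool]:
    """Steepest OLS slope over sliding windows of the smoothed curve.

    Returns (slope per hour, inflection_time_s, multiphasic_warning).  The
    inflection time is the centre of the maximizing window (ties broken
    earliest).  The warning fires when a second local slope maximum reaches
    80% of the global one — growth with multiple phases can make the single
    steepest window a poor rate summary.
    """
    times_h = np.asarray(times_s, float) / 3600.0
    curve = np.asarray(curve, float)
    if len(curve) < window_points:
        raise UndefinedValueError(
            f"need >= {window_points} points for the slope window")
    smooth = moving_average_smooth(curve, smooth_window)
    n_win = len(curve) - window_points + 1
    slopes = np.empty(n_win)
    centers = np.empty(n_win)
    for i in range(n_win):
        t = times_h[i:i + window_points]
        y = smooth[i:i + window_points]
        ok = np.isfinite(y)
        if ok.sum() < 2:
            slopes[i] = -np.inf
            centers[i] = t.mean()
            continue
        tc = t[ok] - t[ok].mean()
        slopes[i] = float(tc @ (y[ok] - y[ok].mean()) / (tc @ tc))
        centers[i] = t.mean()
    best = int(np.argmax(slopes))  # argmax returns the earliest tie
    # multiphasic warning: the window-slope series re-enters the near-maximal
    # band (>= 80% of the global max) after having left it, i.e. there are
    # two separated fast-growth phases
    warn = False
    if n_win >= 3 and slopes[best] > 0:
        strong = slopes >= MULTIPHASIC_WARN_FRACTION * slopes[best]
        runs = np.flatnonzero(np.diff(strong.astype(int)) == 1).size + \
            int(strong[0])
        warn = runs > 1
    return float(slopes[best]), float(centers[best] * 3600.0), warn


def lag_time(times_s, curve, printed_mass: float,
             fraction: float = DEFAULT_LAG_FRACTION,
             smooth_window: int = DEFAULT_SMOOTH_WINDOW) -> float:
    """Seconds until the smoothed curve exceeds printed_mass + f·(plateau − printed_mass).

    The plateau is the maximum of the smoothed curve; the crossing is found
    by linear interpolation between the bracketing timepoints.  A curve
    already above the threshold at its first reading has zero lag; a curve
    that never crosses (a dead colony) has no defined lag.
    """
    times_s = np.asarray(times_s, float)
    curve = np.asarray(curve, float)
    smooth = moving_average_smooth(curve, smooth_window)
    ok = np.isfinite(smooth)
    if not ok.any():
        raise UndefinedValueError("all readings missing")
    plateau = float(np.nanmax(smooth))
    threshold = printed_mass + fraction * (plateau - printed_mass)
    above = np.flatnonzero(ok & (smooth > threshold))
    if len(above) == 0:
        raise UndefinedValueError("curve never exceeds the lag threshold")
    i = above[0]
    if i == 0:
        return 0.0
    t0, t1 = times_s[i - 1], times_s[i]
    v0, v1 = smooth[i - 1], smooth[i]
    if not np.isfinite(v0) or v1 == v0:
        return float(t1)
    return float(t0 + (threshold - v0) / (v1 - v0) * (t1 - t0))


# ---------------------------------------------------------------------------
# Controlled experiments (treatment / control pairing)
# ---------------------------------------------------------------------------

@dataclass
class ControlledExperiment:
    """A treatment plate paired with its control, by position and strain."""

    treatment: ProcessedSeries
    control: ProcessedSeries

    def __post_init__(self) -> None:
        t, c = self.treatment.base, self.control.base
        if t.geometry != c.geometry:
            raise CalculatorError("treatment and control geometries differ")
        if t.layout is not None and c.layout is not None:
            ts = t.layout.table["strain"]
            cs = c.layout.table["strain"]
            if not ts.equals(cs):
                raise CalculatorError(
                    "treatment and control layouts assign different strains")


def treatment_ratio(pair: ControlledExperiment, label: str, window_s,
                    epsilon: float = DEFAULT_EPSILON) -> float:
    """Windowed average under treatment divided by the same under control.

    The control average must exceed ``epsilon`` (default 0.05 absorbance);
    dividing by a near-zero control is suppressed as undefined.
    """
    t_avg = average_without_agar(pair.treatment.times_s, pair.treatment.curve(label),
                                 window_s)
    c_avg = average_without_agar(pair.control.times_s, pair.control.curve(label),
                                 window_s)
    if c_avg <= epsilon:
        raise UndefinedValueError(
            f"control average {c_avg:.3g} <= epsilon {epsilon}")
    return t_avg / c_avg


# ---------------------------------------------------------------------------
# Registry and runner
# ---------------------------------------------------------------------------

@dataclass
class CalculatorSpec:
    """A calculator invocation: its registry name plus the parameters it needs."""

    name: str
    window_h: tuple[float, float] | None = None
    smooth_window: int = DEFAULT_SMOOTH_WINDOW
    slope_window_points: int = DEFAULT_SLOPE_WINDOW_POINTS
    lag_fraction: float = DEFAULT_LAG_FRACTION
    epsilon: float = DEFAULT_EPSILON

    @property
    def window_s(self) -> tuple[float, float] | None:
        if self.window_h is None:
            return None
        return (self.window_h[0] * 3600.0, self.window_h[1] * 3600.0)


_REGISTRY: dict[str, dict] = {}


def register_calculator(name: str, needs_window: bool = False,
                        needs_pair: bool = False):
    """Register a calculator under a camel-case name (decorator)."""
    def deco(fn: Callable):
        _REGISTRY[name] = {"fn": fn, "needs_window": needs_window,
                           "needs_pair": needs_pair}
        return fn
    return deco


def registered_calculators() -> list[str]:
    return sorted(_REGISTRY)


register_calculator("AverageWithoutAgarCalc", needs_window=True)(
    lambda proc, label, spec: average_without_agar(
        proc.times_s, proc.curve(label), spec.window_s))
register_calculator("MaximumWithoutAgarCalc")(
    lambda proc, label, spec: maximum_without_agar(proc.times_s, proc.curve(label)))
register_calculator("MaxChangeCalc")(
    lambda proc, label, spec: max_change(proc.times_s, proc.curve(label)))
register_calculator("MaxSlopeCalc")(
    lambda proc, label, spec: max_slope(proc.times_s, proc.curve(label),
                                        spec.smooth_window,
                                        spec.slope_window_points))
register_calculator("LagCalc")(
    lambda proc, label, spec: lag_time(
        proc.times_s, proc.curve(label),
        proc.printed_mass[proc.base.geometry.label_index(label)],
        spec.lag_fraction, spec.smooth_window))
register_calculator("TreatmentRatioCalc", needs_window=True, needs_pair=True)(
    lambda pair, label, spec: treatment_ratio(pair, label, spec.window_s,
                                              spec.epsilon))

DEFAULT_SPECS = (
    CalculatorSpec("AverageWithoutAgarCalc", window_h=(15.0, 17.0)),
    CalculatorSpec("MaximumWithoutAgarCalc"),
    CalculatorSpec("MaxChangeCalc"),
    CalculatorSpec("MaxSlopeCalc"),
    CalculatorSpec("LagCalc"),
)


@dataclass
class PhenotypeResult:
    """Per-well calculator values, with reasons for any undefined entries.

    ``table`` is indexed by well label; MaxSlopeCalc contributes three
    columns (value, inflection_time_s, multiphasic warning).  ``scatter``
    holds the printed-mass vs lag pairs emitted for the default diagnostic
    scatterplot (lag often correlates with printed mass).
    """

    table: pd.DataFrame
    reasons: dict[tuple[str, str], str]
    scatter: pd.DataFrame | None = None


def run_calculators(subject, specs=DEFAULT_SPECS) -> PhenotypeResult:
    """Apply calculator specs to every non-empty well.

    ``subject`` is a :class:`ProcessedSeries`, or a
    :class:`ControlledExperiment` when any spec needs a treatment/control
    pair.  Unknown calculator names raise a configuration error listing the
    registered names; windowed calculators reject specs without a window.
    """
    specs = list(specs)
    for spec in specs:
        if spec.name not in _REGISTRY:
            raise ConfigError(f"unknown calculator {spec.name!r}; registered: "
                              f"{registered_calculators()}")
        if _REGISTRY[spec.name]["needs_window"] and spec.window_h is None:
            raise ConfigError(f"{spec.name} requires a time window")
        if _REGISTRY[spec.name]["needs_pair"] and \
                not isinstance(subject, ControlledExperiment):
            raise ConfigError(f"{spec.name} requires a treatment/control pair")

    proc = subject.treatment if isinstance(subject, ControlledExperiment) else subject
    if proc.base.layout is not None:
        wells = proc.base.layout.non_empty_labels()
    else:
        wells = proc.labels
    columns: dict[str, dict] = {}
    reasons: dict[tuple[str, str], str] = {}
    for spec in specs:
        entry = _REGISTRY[spec.name]
        target = subject if entry["needs_pair"] else proc
        vals, infl, warns = {}, {}, {}
        for lab in wells:
            try:
                result = entry["fn"](target, lab, spec)
            except UndefinedValueError as exc:
                vals[lab] = np.nan
                reasons[(lab, spec.name)] = str(exc)
                continue
            if spec.name == "MaxSlopeCalc":
                vals[lab], infl[lab], warns[lab] = result
            else:
                vals[lab] = result
        columns[spec.name] = vals
        if spec.name == "MaxSlopeCalc":
            columns["inflection_time_s"] = infl
            columns["multiphasic_warning"] = warns
    table = pd.DataFrame(columns, index=pd.Index(wells, name="position"))
    scatter = None
    if "LagCalc" in table.columns:
        pm = [proc.printed_mass[proc.base.geometry.label_index(lab)] for lab in wells]
        scatter = pd.DataFrame({"printed_mass": pm,
                                "lag_s": table["LagCalc"].to_numpy()},
                               index=table.index)
    return PhenotypeResult(table, reasons, scatter)
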