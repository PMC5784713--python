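"""Absorbance-to-cell-count calibration and method comparison.

Vertical absorbance through a colony on agar is a proxy for a roughly
hemispherical cell mass, so its relation to cell count is exponential rather
than linear.  The empirically determined calibrations are

    solid media (plate reader):  P = 77900 * exp(1.76 * A)
    liquid spectrophotometry:    P = 8000 * (725 * A + 7)

with A the agar-subtracted absorbance (or liquid OD600) and P the predicted
cell count.  The refitting helpers reproduce the least-squares conventions
behind those formulas; Bland–Altman limits of agreement compare two
prediction methods on shared samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .plate_core import PlatePhenError


class CalibrationError(PlatePhenError):
    pass


SOLID_PREFACTOR = 77900.0
SOLID_RATE = 1.76
LIQUID_SCALE = 8000.0
LIQUID_SLOPE = 725.0
LIQUID_OFFSET = 7.0

#: Liquid readings above this OD600 need a 1:10 dilution read instead.
DILUTION_THRESHOLD = 1.0


@dataclass
class CalibrationModel:
    """Fitted calibration: P = a·exp(b·A) (solid) or P = a·A + b (liquid)."""

    kind: str            # "exponential_solid" | "linear_liquid"
    a: float
    b: float
    r_squared: float = float("nan")

    def predict(self, A) -> np.ndarray | float:
        A = np.asarray(A, dtype=float)
        if self.kind == "exponential_solid":
            out = self.a * np.exp(self.b * A)
        elif self.kind == "linear_liquid":
            out = self.a * A + self.b
        else:
            raise CalibrationError(f"unknown calibration kind {self.kind!r}")
        return float(out) if out.ndim == 0 else out


def predict_count_solid(A) -> float | np.ndarray:
    """Predicted cells under a colony from agar-subtracted absorbance A."""
    out = SOLID_PREFACTOR * np.exp(SOLID_RATE * np.asarray(A, dtype=float))
    return float(out) if out.ndim == 0 else out


def predict_count_liquid(A) -> float | np.ndarray:
    """Predicted cells/ml-scale count from a liquid OD600 reading."""
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise CalibrationError("liquid OD600 must be nonnegative")
    out = LIQUID_SCALE * (LIQUID_SLOPE * A + LIQUID_OFFSET)
    return float(out) if out.ndim == 0 else out


def hemocytometer_count(C: float, S: int) -> float:
    """Cells from a counting-chamber tally: 10,000 × C × (25/S).

    C cells counted over S of the chamber's 25 subsquares.
    """
    if S <= 0 or S > 25:
        raise CalibrationError(f"subsquares S must be in 1..25, got {S}")
    if C < 0:
        raise CalibrationError("cell count C must be nonnegative")
    return 10000.0 * C * (25.0 / S)


def requires_dilution(reading: float) -> bool:
    """Spectrophotometer readings above OD600 = 1 are unreliable; dilute 1:10."""
    return reading > DILUTION_THRESHOLD


def dilution_correct(reading: float, dilution_factor: float) -> float:
    """Scale a diluted reading back up (e.g. a 1:10 dilution → factor 10)."""
    if dilution_factor < 1:
        raise CalibrationError("dilution factor must be >= 1")
    return reading * dilution_factor


def fit_exponential_calibration(pairs, method: str = "log-linear"
                                ) -> CalibrationModel:
    """Fit P = a·exp(b·A) to (A, count) pairs.

    The default is unweighted OLS on ln(count) — the spreadsheet-LINEST
    analog of an exponential trend fit, with R² reported on the log scale.
    ``method="nls"`` instead minimizes squared error on the raw count scale
    (sensitivity alternative), seeded from the log-linear fit.
    """
    A = np.asarray([p[0] for p in pairs], dtype=float)
    counts = np.asarray([p[1] for p in pairs], dtype=float)
    if len(A) < 3:
        raise CalibrationError("need >= 3 pairs for the exponential fit")
    if np.any(counts <= 0):
        raise CalibrationError("cell counts must be positive for the log fit")
    fit = stats.linregress(A, np.log(counts))
    a, b = math.exp(fit.intercept), float(fit.slope)
    r2 = float(fit.rvalue) ** 2
    if method == "log-linear":
        return CalibrationModel("exponential_solid", a, b, r2)
    if method == "nls":
        (a_n, b_n), _ = optimize.curve_fit(lambda x, aa, bb: aa * np.exp(bb * x),
                                           A, counts, p0=(a, b), maxfev=10000)
        pred = a_n * np.exp(b_n * A)
        ss_res = float(np.sum((counts - pred) ** 2))
        ss_tot = float(np.sum((counts - counts.mean()) ** 2))
        r2_raw = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        return CalibrationModel("exponential_solid", float(a_n), float(b_n), r2_raw)
    raise CalibrationError(f"unknown fit method {method!r}")


def fit_linear_calibration(pairs) -> CalibrationModel:
    """Unweighted OLS of count on A: count = a·A + b."""
    A = np.asarray([p[0] for p in pairs], dtype=float)
    counts = np.asarray([p[1] for p in pairs], dtype=float)
    if len(A) < 2:
        raise CalibrationError("need >= 2 pairs for the linear fit")
    if np.allclose(A, A[0]):
        raise CalibrationError("degenerate fit: all absorbance values equal")
    fit = stats.linregress(A, counts)
    return CalibrationModel("linear_liquid", float(fit.slope),
                            float(fit.intercept), float(fit.rvalue) ** 2)


@dataclass
class BlandAltman:
    """Limits-of-agreement comparison of two measurement methods.

    bias = mean(P1 − P2); limits = bias ± 1.96·SD of the differences.
    ``table`` lists the per-pair mean and difference for plotting.
    """

    bias: float
    loa_low: float
    loa_high: float
    table: pd.DataFrame


def bland_altman(pairs) -> BlandAltman:
    """Bland–Altman agreement between paired predictions (P1, P2)."""
    P1 = np.asarray([p[0] for p in pairs], dtype=float)
    P2 = np.asarray([p[1] for p in pairs], dtype=float)
    if len(P1) < 2:
        raise CalibrationError("need >= 2 pairs for limits of agreement")
    diff = P1 - P2
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    table = pd.DataFrame({"mean": (P1 + P2) / 2.0, "difference": diff})
    return BlandAltman(bias, bias - 1.96 * sd, bias + 1.96 * sd, table)


def load_paired_measurements(stream) -> pd.DataFrame:
    """Read a paired-measurement CSV (well, A_solid, A_liquid, dilution_factor, C, S).

    Liquid readings are dilution-corrected; hemocytometer counts are derived
    from C and S where present.
    """
    import io
    text = stream.read() if hasattr(stream, "read") else stream
    df = pd.read_csv(io.StringIO(text), comment="#")
    need = {"well", "A_solid", "A_liquid"}
    if not need <= set(df.columns):
        raise CalibrationError(f"paired table needs columns {sorted(need)}")
    factor = df["dilution_factor"] if "dilution_factor" in df.columns else 1.0
    df["A_liquid_corrected"] = df["A_liquid"] * np.asarray(factor, dtype=float)
    if {"C", "S"} <= set(df.columns):
        df["hemocytometer"] = [hemocytometer_count(c, int(s))
                               for c, s in zip(df["C"], df["S"])]
    return df
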