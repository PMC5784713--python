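"""Phenotype calculators: windowed averages, slopes, lags and treatment ratios."""

import numpy as np
import pytest

from platephen.phenotype_calculators import (CalculatorSpec, ConfigError,
                                             ControlledExperiment,
                                             UndefinedValueError,
                                             average_without_agar, lag_time,
                                             max_change, max_slope,
                                             registered_calculators,
                                             run_calculators, treatment_ratio)
from platephen.plate_core import ExperimentSeries, PlateGeometry
from platephen.preprocess import subtract_agar
from platephen.synthetic_data import GrowthParams, default_times_s, logistic_signal

H = 3600.0


def test_average_without_agar():
    times = np.array([0.0, 1.0, 2.0]) * H
    assert average_without_agar(times, [1.0, 2.0, 3.0], (1 * H, 2 * H)) == 2.5
    assert average_without_agar(times, [2.0, 2.0, 2.0], (0.0, 9 * H)) == 2.0
    with pytest.raises(UndefinedValueError):
        average_without_agar(times, [1.0, 2.0, 3.0], (5 * H, 6 * H))


def test_max_change():
    times = np.arange(5) * H
    assert max_change(times, [0.1, 0.3, 0.5, 0.65, 0.72]) == pytest.approx(0.62)
    assert max_change(times, np.full(5, 1.0)) == 0.0
    # rise then fall: change taken at the maximum, not the endpoint
    assert max_change(times, [0.1, 0.5, 0.9, 0.6, 0.3]) == pytest.approx(0.8)


def test_max_slope_linear_ramp():
    times = np.arange(13) * H
    slope, t_infl, warn = max_slope(times, 0.1 * times / H)
    assert slope == pytest.approx(0.1)
    assert not warn


def test_max_slope_recovers_logistic_rate():
    """On a noiseless logistic sampled every 20 min, the steepest window slope
    is rK/4 within 2% and the inflection lands at tm."""
    params = GrowthParams(K=2.0, r=0.4, tm=12.0, A0=0.0, dip_depth=0.0,
                          sigma0=0.0, sigma1=0.0, agar_base=0.0)
    times = default_times_s(65.0)
    curve = logistic_signal(params, times)
    slope, t_infl, warn = max_slope(times, curve)
    assert slope == pytest.approx(params.r * params.K / 4.0, rel=0.02)
    assert abs(t_infl - params.tm * H) <= 1200.0
    assert not warn


def test_max_slope_biphasic_warns_and_picks_steeper_phase():
    t_h = np.arange(0, 40, 1 / 3)
    phase1 = 1.0 / (1.0 + np.exp(-1.2 * (t_h - 8.0)))    # max slope 0.30/h
    phase2 = 1.3 / (1.0 + np.exp(-1.0 * (t_h - 28.0)))   # max slope 0.325/h
    slope, t_infl, warn = max_slope(t_h * H, phase1 + phase2)
    assert warn
    assert abs(t_infl / H - 28.0) < 2.0  # the steeper (second) phase wins


def test_max_slope_needs_enough_points():
    with pytest.raises(UndefinedValueError):
        max_slope(np.arange(3) * H, [0.0, 0.1, 0.2])


def test_lag_time_examples():
    times = np.arange(6) * H
    # already above threshold at t=0
    assert lag_time(times, np.full(6, 1.0), printed_mass=0.0,
                    smooth_window=1) == 0.0
    # step 0.1 -> 1.1 between 2 h and 3 h; threshold 0.15 crosses at 2.05 h
    curve = np.array([0.1, 0.1, 0.1, 1.1, 1.1, 1.1])
    lag = lag_time(times, curve, printed_mass=0.1, fraction=0.05,
                   smooth_window=1)
    assert lag == pytest.approx(2.05 * H)
    with pytest.raises(UndefinedValueError):
        lag_time(times, np.full(6, 0.2), printed_mass=0.2, smooth_window=1)


def test_lag_time_nondecreasing_in_fraction():
    params = GrowthParams(K=2.0, r=0.4, tm=12.0, A0=0.05, dip_depth=0.0,
                          sigma0=0.0, sigma1=0.0, agar_base=0.0)
    times = default_times_s(40.0)
    curve = logistic_signal(params, times)
    lags = [lag_time(times, curve, 0.05, fraction=f)
            for f in (0.02, 0.05, 0.1, 0.2, 0.5)]
    assert all(a <= b for a, b in zip(lags, lags[1:]))


def _uniform_processed(value, agar=0.5, n_t=73, geometry=96, hours=24.0):
    g = PlateGeometry(geometry)
    times = np.linspace(0.0, hours * H, n_t)
    raw = np.full((n_t, g.n_wells), float(value))
    series = ExperimentSeries("P1", g, np.full(g.n_wells, agar), times, raw,
                              ["r"])
    return subtract_agar(series)


def test_treatment_ratio_identity_and_scaling():
    control = _uniform_processed(2.5)  # corrected 2.0
    pair = ControlledExperiment(_uniform_processed(2.5), control)
    assert treatment_ratio(pair, "A1", (15 * H, 17 * H)) == pytest.approx(1.0)
    pair = ControlledExperiment(_uniform_processed(1.0), control)  # 0.5 / 2.0
    assert treatment_ratio(pair, "A1", (15 * H, 17 * H)) == pytest.approx(0.25)


def test_treatment_ratio_suppressed_below_epsilon():
    pair = ControlledExperiment(_uniform_processed(1.0),
                                _uniform_processed(0.52))  # control avg 0.02
    with pytest.raises(UndefinedValueError, match="epsilon"):
        treatment_ratio(pair, "A1", (15 * H, 17 * H))


def test_sensitive_vs_resistant_ratio_separation():
    """Simulated paraquat-style pair: a sensitive strain's treatment ratio is
    far below a resistant strain's (seed 5)."""
    from platephen.plate_core import combine_runs, ArrayLayout
    from platephen.synthetic_data import simulate_plate
    rng = np.random.default_rng(5)
    g = PlateGeometry(96)
    layout = ArrayLayout.empty(g)
    layout.table.at["A1", "strain"] = "sens"
    layout.table.at["A2", "strain"] = "res"
    times = default_times_s(24.0)
    base = {"sens": GrowthParams(K=2.0), "res": GrowthParams(K=2.0)}
    agar_c, growth_c, _ = simulate_plate(layout, base, rng, times_s=times)
    control = subtract_agar(combine_runs([growth_c], agar_c, layout))
    treat_params = {"sens": GrowthParams(K=0.15), "res": GrowthParams(K=1.8)}
    agar_t, growth_t, _ = simulate_plate(layout, treat_params, rng, times_s=times)
    treatment = subtract_agar(combine_runs([growth_t], agar_t, layout))
    pair = ControlledExperiment(treatment, control)
    window = (15 * H, 17 * H)
    sens = treatment_ratio(pair, "A1", window)
    res = treatment_ratio(pair, "A2", window)
    assert sens < 0.3 * res


def test_calculators_ignore_duplicated_points_outside_window():
    times = np.array([15.0, 16.0, 17.0]) * H
    curve = np.array([1.0, 2.0, 3.0])
    base = average_without_agar(times, curve, (15 * H, 17 * H))
    times2 = np.concatenate([times, [30 * H, 31 * H]])
    curve2 = np.concatenate([curve, [2.0, 2.0]])
    assert average_without_agar(times2, curve2, (15 * H, 17 * H)) == base


def test_run_calculators_selection_and_unknown_name(processed):
    result = run_calculators(processed,
                             [CalculatorSpec("AverageWithoutAgarCalc",
                                             window_h=(15.0, 17.0))])
    assert list(result.table.columns) == ["AverageWithoutAgarCalc"]
    with pytest.raises(ConfigError, match="FooCalc"):
        run_calculators(processed, [CalculatorSpec("FooCalc")])
    with pytest.raises(ConfigError, match="window"):
        run_calculators(processed, [CalculatorSpec("AverageWithoutAgarCalc")])


def test_run_calculators_full_default_smoke(processed):
    """The default calculator set runs over a simulated plate without errors
    and populates every column for every occupied well."""
    result = run_calculators(processed)
    assert set(result.table.index) == \
        set(processed.base.layout.non_empty_labels())
    for name in ("AverageWithoutAgarCalc", "MaximumWithoutAgarCalc",
                 "MaxChangeCalc", "MaxSlopeCalc", "LagCalc"):
        assert name in result.table.columns
        assert result.table[name].notna().all()
    assert result.scatter is not None
    assert {"printed_mass", "lag_s"} <= set(result.scatter.columns)


def test_windowed_average_hits_plateau(small_plate, processed):
    """Averaging on the plateau of a simulated logistic recovers K + A0."""
    layout = small_plate["layout"]
    lab = layout.non_empty_labels()[0]
    strain = layout.strain_at(lab)
    p = small_plate["params"][strain]
    value = average_without_agar(processed.times_s, processed.curve(lab),
                                 (22 * H, 24 * H))
    assert value == pytest.approx(p.K + p.A0, abs=0.05)


def test_registry_lists_default_calculators():
    names = registered_calculators()
    for expected in ("AverageWithoutAgarCalc", "MaxChangeCalc", "MaxSlopeCalc",
                     "LagCalc", "TreatmentRatioCalc", "MaximumWithoutAgarCalc"):
        assert expected in names
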