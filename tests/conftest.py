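import numpy as np
import pytest

from platephen.plate_core import PlateGeometry, combine_runs
from platephen.preprocess import subtract_agar
from platephen.synthetic_data import (GrowthParams, default_times_s,
                                      random_layout, simulate_plate)


@pytest.fixture(scope="session")
def small_plate():
    """A seeded 96-well plate: 24 strains x 2 replicates, 24 h of readings."""
    rng = np.random.default_rng(1)
    geometry = PlateGeometry(96)
    layout = random_layout(geometry, 24, 2, rng)
    params = {f"S{k:03d}": GrowthParams(K=1.0 + 0.05 * k, r=0.4, tm=10.0)
              for k in range(1, 25)}
    agar_run, growth_run, truth = simulate_plate(
        layout, params, rng, times_s=default_times_s(24.0))
    return {"layout": layout, "agar_run": agar_run, "growth_run": growth_run,
            "truth": truth, "params": params}


@pytest.fixture(scope="session")
def processed(small_plate):
    series = combine_runs([small_plate["growth_run"]], small_plate["agar_run"],
                          small_plate["layout"])
    return subtract_agar(series)
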