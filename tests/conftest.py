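import numpy as np
import pytest

from gtscreen import simulate
from gtscreen.simulate import CompoundEffect, GrowthParams


@pytest.fixture(scope="session")
def small_layout():
    """One 96-well plate per sex: 16 compounds x 4 replicates + 16 controls."""
    layout = simulate.generate_plate_layout(
        16, compounds_per_plate=16, replicates=4, controls_per_plate=16,
        plate_format=96, seed=11,
    )
    simulate.validate_layout(layout)
    return layout


@pytest.fixture(scope="session")
def small_screen(small_layout):
    """Measurements for the small plate with one planted hypo and one hyper."""
    effects = {
        "CPD01": CompoundEffect(effect_male=0.25, effect_female=0.25,
                                family="PLK", size_shift_male=-40,
                                size_shift_female=-40),
        "CPD02": CompoundEffect(effect_male=2.0, effect_female=2.0, family="RAF"),
    }
    growth = GrowthParams(count_cv=0.05)
    measurements = simulate.simulate_screen_counts(
        small_layout, effects, growth, days=6, seed=11
    )
    return measurements, effects


def constructed_plate(n_compound_wells=160, n_controls=160,
                      base=1000.0, spread=10.0, sex="male"):
    """Hand-built single-plate layout + measurements with known median/MAD.

    Compound wells alternate base±spread (median = base, MAD = spread);
    control wells start at base and can be displaced by the caller.
    """
    n_compounds = n_compound_wells // 4
    layout = simulate.generate_plate_layout(
        n_compounds, compounds_per_plate=n_compounds, replicates=4,
        controls_per_plate=n_controls, plate_format=384, seed=0,
    )
    layout = layout[layout["sex"] == sex].reset_index(drop=True)
    meas = layout[layout["role"] != "empty"][["plate_id", "well", "sex", "role"]].copy()
    counts = np.where(
        meas["role"].eq("compound"),
        np.where(np.arange(len(meas)) % 2 == 0, base - spread, base + spread),
        base,
    )
    meas["cell_count"] = counts
    meas["mean_nuclear_area"] = 100.0
    meas["n_fields"] = 4
    return layout, meas.drop(columns="role").reset_index(drop=True)
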