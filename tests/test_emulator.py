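import numpy as np
import pytest

from wheatsa import (
    PARAMETER_CODES,
    MaturityError,
    generate_weather,
    run_emulator,
    to_physical_matrix,
)
from wheatsa.emulator import reference_demand, simulate_batch, simulate_cells
from wheatsa.synthetic_env import TREATMENT_TABLE, TreatmentPlan, WeatherSeries


def _zero_radiation_weather():
    w = generate_weather(seed=1)
    return WeatherSeries(
        day=w.day, maxt=w.maxt, mint=w.mint, rain=w.rain,
        radn=np.zeros_like(w.radn),
    )


def test_no_radiation_means_no_growth(midpoints, plan_w1):
    out = run_emulator(midpoints, _zero_radiation_weather(), plan_w1)
    assert out.wagt == 0.0
    assert out.grain_yield == 0.0


def test_determinism_bit_identical(midpoints, weather, plan_w1):
    a = run_emulator(midpoints, weather, plan_w1)
    b = run_emulator(midpoints, weather, plan_w1)
    assert (a.wagt, a.grain_yield) == (b.wagt, b.grain_yield)


def test_radiation_use_efficiency_is_monotone(midpoints, weather, plan_w1, specs):
    base = run_emulator(midpoints, weather, plan_w1)
    richer = dict(midpoints)
    richer["R1"] = midpoints["R1"] * 1.05
    assert richer["R1"] <= {s.code: s for s in specs}["R1"].upper
    up = run_emulator(richer, weather, plan_w1)
    assert up.wagt >= base.wagt


def test_yield_bounded_by_biomass_over_random_draws(specs, weather, plan_w1):
    rng = np.random.default_rng(42)
    P = to_physical_matrix(rng.random((1000, 21)), specs)
    wagt, grain_yield = simulate_batch(P, weather, plan_w1)
    assert np.all(np.isfinite(wagt)) and np.all(np.isfinite(grain_yield))
    assert np.all(grain_yield >= 0.0)
    assert np.all(grain_yield <= wagt + 1e-9)


def test_stage_order_is_strict(specs, weather, plan_w1):
    rng = np.random.default_rng(3)
    P = to_physical_matrix(rng.random((300, 21)), specs)
    _, _, detail = simulate_batch(P, weather, plan_w1, return_detail=True)
    assert np.all(detail["day_jointing"] < detail["day_flowering"])
    assert np.all(detail["day_flowering"] < detail["day_grain_fill"])
    assert np.all(detail["day_grain_fill"] < detail["day_maturity"])


def test_more_water_never_decreases_biomass(midpoints, weather, specs):
    """Raising any phase's lower irrigation limit (wetter regime) cannot
    reduce WAGT at baseline parameters."""
    rng = np.random.default_rng(8)
    P = to_physical_matrix(rng.random((50, 21)), specs)
    for phase_idx in range(2, 6):  # greening .. grain filling
        dry = list(TREATMENT_TABLE["W1"])
        wet = list(TREATMENT_TABLE["W1"])
        dry[phase_idx] = 50
        wet[phase_idx] = 80
        plan_dry = TreatmentPlan("dryer", tuple(float(v) for v in dry))
        plan_wet = TreatmentPlan("wetter", tuple(float(v) for v in wet))
        w_dry, _ = simulate_batch(P, weather, plan_dry)
        w_wet, _ = simulate_batch(P, weather, plan_wet)
        assert np.all(w_wet >= w_dry - 1e-9)


def test_weather_too_short_raises_instead_of_truncating(midpoints, plan_w1):
    short = generate_weather(seed=1, season_days=120)
    with pytest.raises(MaturityError):
        run_emulator(midpoints, short, plan_w1)


def test_all_phenology_corners_mature(specs, weather, plan_w1):
    rng = np.random.default_rng(0)
    U = rng.random((200, 21))
    for val in (0.0, 1.0):
        U_corner = U.copy()
        for code in ("T1", "T2", "T3", "T4", "P4", "V1"):
            U_corner[:, PARAMETER_CODES.index(code)] = val
        wagt, grain_yield = simulate_batch(
            to_physical_matrix(U_corner, specs), weather, plan_w1
        )
        assert np.all(np.isfinite(wagt))


def test_incomplete_parameter_set_rejected(midpoints, weather, plan_w1):
    partial = dict(midpoints)
    del partial["K"]
    with pytest.raises(ValueError, match="K"):
        run_emulator(partial, weather, plan_w1)


def test_cell_ensemble_matches_single_batches(specs, weathers, plans):
    rng = np.random.default_rng(5)
    P = to_physical_matrix(rng.random((8, 21)), specs)
    cells = [(weathers[y], p) for y in weathers for p in plans[:2]]
    wagt, grain_yield = simulate_cells(P, cells)
    for ci, (w, plan) in enumerate(cells):
        a, b = simulate_batch(P, w, plan)
        assert np.allclose(wagt[:, ci], a)
        assert np.allclose(grain_yield[:, ci], b)


class TestReferenceDemand:
    def test_zero_forcing_gives_zero_demand(self):
        assert reference_demand(0.0, 0.0, 0.0) == 0.0

    def test_monotone_in_radiation_and_temperature(self):
        base = reference_demand(20.0, 10.0, 15.0)
        assert reference_demand(20.0, 10.0, 30.0) >= base
        assert reference_demand(26.0, 16.0, 15.0) >= base

    def test_finite_and_nonnegative_for_generated_weather(self):
        w = generate_weather(seed=2)
        d = reference_demand(w.maxt, w.mint, w.radn)
        assert np.all(np.isfinite(d)) and np.all(d >= 0.0)
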