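import numpy as np
import pytest

from wheatsa import run_emulator
from wheatsa.synthetic_env import (
    PHASES,
    TREATMENT_TABLE,
    SoilProfile,
    WeatherSeries,
    build_treatment,
    generate_observations,
    generate_weather,
)


class TestWeather:
    def test_identical_seed_gives_identical_series(self):
        a = generate_weather(seed=3)
        b = generate_weather(seed=3)
        for col in ("maxt", "mint", "rain", "radn"):
            assert np.array_equal(getattr(a, col), getattr(b, col))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_physical_invariants(self, seed):
        w = generate_weather(seed=seed)
        assert np.all(w.maxt >= w.mint)
        assert np.all(w.rain >= 0) and np.all(w.radn >= 0)

    @pytest.mark.parametrize("seed", [0, 101, 102, 103])
    def test_annualized_climate_matches_arid_site(self, seed):
        # the default seed and the three bundled study seasons
        w = generate_weather(seed=seed)
        assert 150.0 <= w.annual_precip_mm <= 230.0
        assert 4.5 <= w.annual_mean_temp_c <= 8.5

    def test_short_season_rejected(self):
        with pytest.raises(ValueError):
            generate_weather(seed=0, season_days=10)

    def test_met_file_round_trip(self, tmp_path):
        w = generate_weather(seed=5, season_days=120)
        path = tmp_path / "season.met.csv"
        w.write(path)
        again = WeatherSeries.read(path)
        assert np.allclose(again.tmean, w.tmean)
        assert again.season_days == 120


class TestSoilAndTreatments:
    def test_soil_profile_defaults_and_capacity(self):
        soil = SoilProfile()
        assert soil.field_capacity == 26.15
        assert soil.bulk_density == 1.62
        assert soil.fc_mm == pytest.approx(156.9)
        with pytest.raises(ValueError):
            SoilProfile(field_capacity=0.0)

    def test_treatment_table_reproduces_all_42_cells(self):
        expected = {
            "W1": (65, 65, 65, 65, 65, 65, 65),
            "W2": (65, 65, 65, 65, 50, 50, 65),
            "W3": (65, 65, 65, 65, 80, 80, 65),
            "W4": (65, 65, 80, 80, 65, 65, 65),
            "W5": (65, 65, 50, 50, 65, 65, 65),
            "W6": (65, 65, 50, 50, 50, 65, 65),
        }
        assert TREATMENT_TABLE == expected
        assert sum(len(v) for v in expected.values()) == 42

    @pytest.mark.parametrize(
        "code,phase,smc",
        [
            ("W1", "seedling", 9.15),
            ("W1", "grain_filling", 9.15),
            ("W3", "heading", 5.23),
            ("W3", "grain_filling", 5.23),
            ("W6", "greening", 13.07),
            ("W6", "heading", 13.07),
            ("W6", "maturity", 9.15),
        ],
    )
    def test_allowable_depletion_from_field_capacity(self, code, phase, smc):
        plan = build_treatment(code)
        assert plan.smc[PHASES.index(phase)] == pytest.approx(smc, abs=0.01)

    def test_unknown_treatment_rejected(self):
        with pytest.raises(KeyError):
            build_treatment("W9")


class TestObservations:
    def test_zero_noise_reproduces_emulator_outputs(self, midpoints, weathers, plans):
        obs = generate_observations(
            run_emulator, midpoints, plans[:2], weathers, noise_sd=0.0, seed=0
        )
        for rec in obs.itertuples():
            plan = plans[0] if rec.treatment == "W1" else plans[1]
            out = run_emulator(midpoints, weathers[rec.year], plan)
            truth = out.wagt if rec.variable == "wagt" else out.grain_yield
            assert rec.value == pytest.approx(truth)

    def test_fixed_seed_is_reproducible(self, midpoints, weathers, plans):
        a = generate_observations(run_emulator, midpoints, plans, weathers, seed=9)
        b = generate_observations(run_emulator, midpoints, plans, weathers, seed=9)
        assert a.equals(b)

    def test_noise_sd_within_chi_square_bounds(self, midpoints, weathers, plans):
        # 18 yield records at sd = 300: sample SD lies in [150, 450]
        obs = generate_observations(
            run_emulator, midpoints, plans, weathers,
            noise_sd=300.0, seed=11, variables=("yield",),
        )
        assert len(obs) == 18
        resid = []
        for rec in obs.itertuples():
            plan = plans[int(rec.treatment[1]) - 1]
            truth = run_emulator(midpoints, weathers[rec.year], plan).grain_yield
            resid.append(rec.value - truth)
        assert 150.0 <= np.std(resid, ddof=1) <= 450.0

    def test_negative_noise_rejected(self, midpoints, weathers, plans):
        with pytest.raises(ValueError):
            generate_observations(
                run_emulator, midpoints, plans, weathers, noise_sd=-1.0
            )
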