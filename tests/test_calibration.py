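import numpy as np
import pytest
from scipy.stats import kstest

from wheatsa import generate_observations, midpoint_defaults, run_emulator
from wheatsa.calibration import (
    MCMCConfig,
    log_likelihood,
    metropolis_unit_cube,
    posterior_point_estimate,
    predict_observations,
    run_mcmc,
)


class TestLogLikelihood:
    def test_perfect_predictions_attain_the_maximum(self):
        o = np.array([100.0, 200.0, 300.0])
        sigma = 10.0
        best = log_likelihood(o, o, sigma)
        assert best == pytest.approx(-1.5 * np.log(2 * np.pi * sigma**2))
        assert log_likelihood(o, o + 1.0, sigma) < best

    def test_direct_substitution_two_observations(self):
        # residuals 10 and 10 at sigma 10: logL = 2(-1/2 log(200 pi)) - 1
        val = log_likelihood([100.0, 200.0], [110.0, 190.0], 10.0)
        assert val == pytest.approx(-np.log(200.0 * np.pi) - 1.0)

    def test_doubling_a_residual_costs_three_halves_r_squared(self):
        sigma, r = 25.0, 40.0
        base = log_likelihood([0.0], [r], sigma)
        doubled = log_likelihood([0.0], [2 * r], sigma)
        assert base - doubled == pytest.approx(3 * r**2 / (2 * sigma**2))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood([1.0], [1.0], 0.0)
        with pytest.raises(ValueError):
            log_likelihood([], [], 1.0)
        with pytest.raises(ValueError):
            log_likelihood([1.0, 2.0], [1.0], 1.0)


class TestSamplerCore:
    def test_flat_target_recovers_the_uniform_prior(self):
        draws, _, rates = metropolis_unit_cube(
            lambda U: np.zeros(len(U)), n_dim=2, chain_length=12_000,
            burn_in_frac=0.2, proposal_scale=0.35, seed=0,
        )
        x = draws[0]
        assert rates[0] > 0.2
        for j in range(2):
            thinned = x[::10, j]  # reduce autocorrelation before the KS test
            assert kstest(thinned, "uniform").statistic < 0.08
            assert abs(x[:, j].mean() - 0.5) < 0.02
            assert abs(x[:, j].var() - 1.0 / 12.0) < 0.01

    def test_gaussian_target_moments(self):
        mu, sd = 0.6, 0.05
        draws, _, _ = metropolis_unit_cube(
            lambda U: -0.5 * ((U[:, 0] - mu) / sd) ** 2,
            n_dim=1, chain_length=50_000, burn_in_frac=0.2,
            proposal_scale=0.05, seed=1,
        )
        x = draws[0, :, 0]
        n_eff = len(x) / 20.0  # generous autocorrelation allowance
        assert abs(x.mean() - mu) < 3 * sd / np.sqrt(n_eff)
        assert abs(x.std() - sd) < 3 * sd / np.sqrt(n_eff)

    def test_fixed_seed_reproduces_the_chain(self):
        lt = lambda U: -0.5 * np.sum((U - 0.5) ** 2, axis=1) / 0.01
        a, _, _ = metropolis_unit_cube(lt, 3, 2000, seed=9)
        b, _, _ = metropolis_unit_cube(lt, 3, 2000, seed=9)
        assert np.array_equal(a, b)


@pytest.fixture(scope="module")
def observations(specs, weathers, plans):
    truth = midpoint_defaults(specs)
    truth.update({"T3": 130.0, "G1": 30.0, "K": 0.45})
    obs = generate_observations(
        run_emulator, truth, plans, weathers, noise_sd=300.0, seed=5
    )
    return truth, obs


@pytest.fixture(scope="module")
def chain(observations, weathers, plans):
    _, obs = observations
    config = MCMCConfig(chain_length=1200, burn_in_frac=0.3, seed=3)
    return run_mcmc(config, obs, weathers, plans)


class TestEmulatorCalibration:
    def test_chain_stays_inside_bounds(self, chain, specs):
        by_code = {s.code: s for s in specs}
        for j, code in enumerate(chain.free_codes):
            col = chain.draws[:, j]
            assert col.min() >= by_code[code].lower
            assert col.max() <= by_code[code].upper
        assert 0.0 < chain.acceptance_rate < 1.0

    def test_pinned_parameters_stay_bit_constant(self, chain, specs):
        mid = midpoint_defaults(specs)
        est = posterior_point_estimate(chain)
        for code in set(mid) - set(chain.free_codes):
            assert est[code] == mid[code]

    def test_map_draw_attains_the_stored_maximum(self, chain):
        est_map = posterior_point_estimate(chain, kind="map")
        j = int(np.argmax(chain.log_posterior))
        for k, code in enumerate(chain.free_codes):
            assert est_map[code] == chain.draws[j, k]

    def test_posterior_mean_tracks_the_generating_grain_set_window(
        self, chain, observations
    ):
        truth, _ = observations
        est = posterior_point_estimate(chain)
        assert abs(est["T3"] - truth["T3"]) / truth["T3"] < 0.10

    def test_prediction_alignment_matches_observation_layout(
        self, observations, weathers, plans, specs
    ):
        truth, obs = observations
        pred = predict_observations(truth, obs, weathers, plans)
        noiseless = generate_observations(
            run_emulator, truth, plans, weathers, noise_sd=0.0, seed=0
        )
        assert np.allclose(pred, noiseless["value"].to_numpy(), rtol=1e-12)
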