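import numpy as np
import pytest

from wheatsa.morris import (
    build_trajectories,
    classify_influential,
    elementary_effects,
    run_morris,
    summarize,
)
from wheatsa.oracles import brute_force_elementary_effects, linear, product


class TestDesign:
    def test_paper_design_arithmetic(self):
        design = build_trajectories(n=63, p=4, t=10, seed=0)
        assert design.n_evaluations == 640

    def test_delta_for_four_levels(self):
        assert build_trajectories(n=3, p=4, t=2, seed=0).delta == pytest.approx(2 / 3)

    @pytest.mark.parametrize("n,p,t,seed", [(5, 4, 6, 0), (21, 4, 10, 3), (3, 6, 4, 1)])
    def test_trajectory_structure(self, n, p, t, seed):
        design = build_trajectories(n=n, p=p, t=t, seed=seed)
        assert design.points.min() >= 0.0 and design.points.max() <= 1.0
        for k in range(t):
            traj = design.trajectory(k)
            moved = []
            for j in range(n):
                dx = traj[j + 1] - traj[j]
                nz = np.nonzero(np.abs(dx) > 1e-12)[0]
                assert len(nz) == 1  # exactly one coordinate per step
                assert abs(dx[nz[0]]) == pytest.approx(design.delta)
                moved.append(nz[0])
            assert sorted(moved) == list(range(n))  # each factor exactly once

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            build_trajectories(n=3, p=5, t=4)  # odd p
        with pytest.raises(ValueError):
            build_trajectories(n=3, p=4, t=1)  # too few repetitions


class TestElementaryEffects:
    def test_linear_model_gives_constant_gradients(self):
        fn = linear(2.0, 3.0)
        design = build_trajectories(n=2, p=4, t=8, seed=1)
        ee = elementary_effects(design, fn(design.points))
        assert np.allclose(ee[:, 0], 2.0)
        assert np.allclose(ee[:, 1], 3.0)

    def test_constant_output_gives_zero_effects(self):
        design = build_trajectories(n=4, p=4, t=5, seed=2)
        ee = elementary_effects(design, np.ones(design.n_evaluations))
        assert np.allclose(ee, 0.0)

    def test_interaction_effects_match_brute_force_replay(self):
        fn = product(2)
        design = build_trajectories(n=2, p=4, t=10, seed=3)
        ee = elementary_effects(design, fn(design.points))
        oracle = brute_force_elementary_effects(fn, design)
        assert np.allclose(ee, oracle)
        # product function leaves an interaction signature
        assert summarize(ee).table["sigma"].iloc[0] > 0

    def test_misaligned_outputs_rejected(self):
        design = build_trajectories(n=2, p=4, t=3, seed=0)
        with pytest.raises(ValueError):
            elementary_effects(design, np.zeros(5))
        bad = np.full(design.n_evaluations, np.nan)
        with pytest.raises(ValueError):
            elementary_effects(design, bad)


class TestSummaryAndClassification:
    def test_constant_effects(self):
        s = summarize(np.array([[2.0], [2.0], [2.0]]), ["a"])
        row = s.table.iloc[0]
        assert row["mu_star"] == pytest.approx(2.0)
        assert row["sigma"] == pytest.approx(0.0)

    def test_sign_cancellation_keeps_mu_star(self):
        s = summarize(np.array([[-3.0], [3.0]]), ["a"])
        row = s.table.iloc[0]
        assert row["mu"] == pytest.approx(0.0)
        assert row["mu_star"] == pytest.approx(3.0)

    def test_linear_coefficients_order_the_ranking(self):
        s = run_morris(linear(1.0, 2.0, 3.0), n=3, t=8, seed=4,
                       factor_names=["x1", "x2", "x3"])
        assert s.ranking == ["x3", "x2", "x1"]
        assert np.allclose(s.table["sigma"], 0.0, atol=1e-12)
        assert np.all(s.table["mu_star"] >= np.abs(s.table["mu"]) - 1e-12)

    def test_influence_rule_mean_threshold(self):
        def mk(mu_stars):
            return summarize(np.array([mu_stars, mu_stars]), None)

        assert classify_influential(mk([10, 1, 1, 1, 1])) == {"x1"}
        assert classify_influential(mk([2, 2, 2, 2])) == set()
        assert classify_influential(mk([5, 4, 1, 1, 1])) == {"x1", "x2"}

    def test_scale_equivariance(self):
        fn = linear(1.0, 4.0)
        design = build_trajectories(n=2, p=4, t=6, seed=5)
        y = fn(design.points)
        s1 = summarize(elementary_effects(design, y)).table
        s3 = summarize(elementary_effects(design, 3.0 * y)).table
        for col in ("mu", "mu_star", "sigma"):
            assert np.allclose(3.0 * s1[col], s3[col])

    def test_single_effect_rejected(self):
        with pytest.raises(ValueError):
            summarize(np.array([[1.0, 2.0]]))
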