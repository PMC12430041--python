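import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wheatsa.concordance import (
    consistency_report,
    rank_sensitivities,
    savage_scores,
    tdcc,
)


class TestSavageScores:
    def test_three_item_scores(self):
        ss = savage_scores([1, 2, 3])
        assert ss[0] == pytest.approx(11 / 6)
        assert ss[1] == pytest.approx(5 / 6)
        assert ss[2] == pytest.approx(1 / 3)

    def test_single_item(self):
        assert savage_scores([1])[0] == pytest.approx(1.0)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(min_value=1, max_value=50), st.randoms(use_true_random=False))
    def test_scores_sum_to_n(self, n, rnd):
        ranks = list(range(1, n + 1))
        rnd.shuffle(ranks)
        assert savage_scores(ranks).sum() == pytest.approx(n)

    def test_ties_share_mean_score_and_preserve_total(self):
        ss = savage_scores([1.5, 1.5, 3.0])
        assert ss[0] == ss[1] == pytest.approx((11 / 6 + 5 / 6) / 2)
        assert ss.sum() == pytest.approx(3.0)

    def test_invalid_ranks_rejected(self):
        with pytest.raises(ValueError):
            savage_scores([1, 1, 1])


class TestTDCC:
    def test_identical_rankings_give_unit_concordance(self):
        for n, m in ((2, 2), (5, 3), (21, 6)):
            ranks = np.tile(np.arange(1, n + 1)[:, None], (1, m)).astype(float)
            res = tdcc(ranks)
            assert res.c_t == pytest.approx(1.0, abs=1e-12)
            assert res.t_stat == pytest.approx(m * (n - 1))

    def test_two_by_two_opposite_rankings_by_direct_substitution(self):
        # ss columns (1.5, 0.5) and (0.5, 1.5); row sums (2, 2);
        # numerator 2^2 + 2^2 - m^2 n = 0, hence C_T = 0 exactly
        res = tdcc(np.array([[1.0, 2.0], [2.0, 1.0]]))
        assert res.c_t == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_significance_flags(self):
        n, m = 21, 6
        ranks = np.tile(np.arange(1, n + 1)[:, None], (1, m)).astype(float)
        res = tdcc(ranks)
        assert res.significant and res.highly_significant
        assert res.dof == n - 1

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            tdcc(np.array([[1.0, 1.0]]))  # n = 1
        with pytest.raises(ValueError):
            tdcc(np.array([[1.0], [2.0]]))  # m = 1

    def test_relabeling_factors_leaves_concordance_unchanged(self):
        rng = np.random.default_rng(0)
        ranks = np.column_stack([rng.permutation(8) + 1 for _ in range(4)]).astype(float)
        perm = rng.permutation(8)
        assert tdcc(ranks[perm]).c_t == pytest.approx(tdcc(ranks).c_t)

    def test_adjacent_swaps_never_increase_concordance(self):
        n = 5
        base = np.arange(1, n + 1, dtype=float)
        for m in (2, 3):
            cols = np.tile(base[:, None], (1, m))
            previous = tdcc(cols).c_t
            work = cols.copy()
            for i in range(n - 1):  # progressively disorder one column
                work[[i, i + 1], 0] = work[[i + 1, i], 0]
                current = tdcc(work).c_t
                assert current <= previous + 1e-12
                previous = current

    def test_chi_square_p_is_conservative_against_permutation_null(self):
        # the chi-squared reference is asymptotic; at small n, m its tail
        # probabilities exceed the exact permutation tails, so significance
        # is never overstated
        rng = np.random.default_rng(1)
        n, m, reps = 6, 3, 10_000
        from scipy.stats import chi2

        ts = np.empty(reps)
        for b in range(reps):
            ranks = np.column_stack(
                [rng.permutation(n) + 1 for _ in range(m)]
            ).astype(float)
            ts[b] = tdcc(ranks).t_stat
        for alpha in (0.10, 0.05, 0.01):
            q = chi2.ppf(1 - alpha, n - 1)
            empirical = (ts >= q).mean()
            mc_se = np.sqrt(alpha * (1 - alpha) / reps)
            assert empirical <= alpha + 3 * mc_se


class TestConsistencyReport:
    def test_shared_ranking_gives_unit_cells(self):
        factors = [f"f{i}" for i in range(21)]
        rankings = {
            "2023/yield": {tr: factors for tr in ("W1", "W2", "W3", "W4", "W5", "W6")}
        }
        rep = consistency_report(rankings, mode="columns")
        assert np.allclose(rep["tdcc"], 1.0)
        assert (rep["p"] < 0.01).all()
        rep_c = consistency_report(rankings, mode="consensus")
        assert len(rep_c) == 6
        assert np.allclose(rep_c["tdcc"], 1.0)

    def test_independent_rankings_average_the_null_mean(self):
        # under unrelated rankings E[C_T] = 1/m exactly (E[T] = n - 1),
        # decaying to zero only as the number of repetitions grows
        rng = np.random.default_rng(2)
        factors = [f"f{i}" for i in range(10)]
        for m in (3, 6):
            vals = []
            for rep in range(200):
                rankings = {
                    "cell": {
                        f"t{j}": list(rng.permutation(factors)) for j in range(m)
                    }
                }
                vals.append(consistency_report(rankings)["tdcc"].iloc[0])
            assert np.mean(vals) == pytest.approx(1.0 / m, abs=0.05)

    def test_rank_sensitivities_orientation(self):
        ranks = rank_sensitivities(np.array([[3.0, 1.0], [1.0, 2.0], [2.0, 3.0]]))
        assert list(ranks[:, 0]) == [1, 3, 2]  # largest measure gets rank 1
        assert list(ranks[:, 1]) == [3, 2, 1]
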