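from itertools import combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from fdconn import stats


class TestAnovaStatistic:
    def test_identical_samples_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert stats.anova_statistic(y, y) == 0.0

    def test_hand_example_squared_pooled_t(self):
        assert stats.anova_statistic([1, 2, 3], [4, 5, 6]) == pytest.approx(13.5)

    def test_equals_classical_f_oneway(self, rng):
        for _ in range(50):
            y = rng.normal(size=rng.integers(2, 10))
            x = rng.normal(size=rng.integers(2, 10))
            expected = sps.f_oneway(y, x).statistic
            assert stats.anova_statistic(y, x) == pytest.approx(expected, rel=1e-10)

    def test_equals_squared_t(self, rng):
        y, x = rng.normal(size=6), rng.normal(size=8)
        t = sps.ttest_ind(y, x, equal_var=True).statistic
        assert stats.anova_statistic(y, x) == pytest.approx(t**2, rel=1e-10)

    def test_zero_variance_sentinels(self):
        assert stats.anova_statistic([1.0, 1.0], [1.0, 1.0]) == 0.0
        assert stats.anova_statistic([1.0, 1.0], [2.0, 2.0]) == np.inf

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            stats.anova_statistic([], [1.0, 2.0])


class TestGlobalStatistic:
    def test_single_column_reduces_to_anova(self, rng):
        y, x = rng.normal(size=(5, 1)), rng.normal(size=(4, 1))
        assert stats.global_statistic(y, x) == pytest.approx(
            stats.anova_statistic(y.ravel(), x.ravel())
        )

    def test_additivity(self):
        Y = np.column_stack([[1, 2, 3], [5, 5, 5]])
        X = np.column_stack([[4, 5, 6], [5, 5, 5]])
        assert stats.global_statistic(Y, X) == pytest.approx(13.5)

    def test_matches_per_link_loop(self, rng):
        Y, X = rng.normal(size=(6, 3)), rng.normal(size=(5, 3))
        expected = sum(
            stats.anova_statistic(Y[:, q], X[:, q]) for q in range(3)
        )
        assert stats.global_statistic(Y, X) == pytest.approx(expected, rel=1e-12)

    def test_column_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            stats.global_statistic(np.zeros((3, 2)), np.zeros((3, 3)))


def _brute_force_p(y, x):
    """Enumerate all C(n, |y|) reassignments of the pooled sample.

    Ties are counted with a tiny relative tolerance so that mathematically
    identical relabelings (e.g. the mirror partition) register as >=.
    """
    data = np.concatenate([y, x])
    n, n_m = len(data), len(y)
    t_obs = stats.anova_statistic(y, x)
    cut = t_obs - 1e-9 * max(1.0, abs(t_obs)) if np.isfinite(t_obs) else t_obs
    count = total = 0
    for idx in combinations(range(n), n_m):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        t = stats.anova_statistic(data[mask], data[~mask])
        count += t >= cut
        total += 1
    return count / total


class TestPermutationTest:
    def test_exhaustive_matches_brute_force(self, rng):
        for _ in range(10):
            y = rng.normal(size=int(rng.integers(2, 5)))
            x = rng.normal(size=int(rng.integers(1, 5)))
            res = stats.permutation_test(y, x)
            assert res.exhaustive
            assert res.raw_p == pytest.approx(_brute_force_p(y, x))

    def test_separated_samples(self):
        res = stats.permutation_test(np.array([0.0, 0.1]), np.array([1.0, 1.1]))
        assert res.raw_p == pytest.approx(_brute_force_p(np.array([0.0, 0.1]), np.array([1.0, 1.1])))
        assert 0 < res.raw_p <= 1

    def test_label_swap_invariance(self, rng):
        y, x = rng.normal(size=4), rng.normal(size=3)
        assert (
            stats.permutation_test(y, x).raw_p
            == stats.permutation_test(x, y).raw_p
        )

    def test_monte_carlo_determinism_and_floor(self, rng):
        y, x = rng.normal(size=12), rng.normal(size=12)
        a = stats.permutation_test(y, x, n_perm=99, seed=3, exhaustive_limit=10)
        b = stats.permutation_test(y, x, n_perm=99, seed=3, exhaustive_limit=10)
        assert not a.exhaustive
        assert a.raw_p == b.raw_p > 0

    def test_null_uniformity(self, rng):
        """Under exchangeability the p-value is roughly uniform."""
        ps = []
        for k in range(200):
            y = rng.normal(size=5)
            x = rng.normal(size=5)
            ps.append(stats.permutation_test(y, x).raw_p)
        assert abs(np.mean(ps) - 0.5) < 0.06
        assert np.mean(np.array(ps) <= 0.05) < 0.12

    def test_bad_n_perm_rejected(self, rng):
        with pytest.raises(ValueError, match="n_perm"):
            stats.permutation_test(
                rng.normal(size=10), rng.normal(size=10), n_perm=0, exhaustive_limit=5
            )


class TestHolm:
    def test_single_p_unchanged(self):
        assert stats.holm_adjust([0.04])[0] == pytest.approx(0.04)

    def test_hand_stepdown(self):
        out = stats.holm_adjust([0.01, 0.02, 0.03])
        assert out == pytest.approx([0.03, 0.04, 0.04])

    def test_all_equal(self):
        assert stats.holm_adjust([0.2] * 4) == pytest.approx([0.8] * 4)
        assert stats.holm_adjust([0.5] * 4) == pytest.approx([1.0] * 4)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(0.001, 1.0, size=int(rng.integers(1, 12)))
            expected = multipletests(p, method="holm")[1]
            assert stats.holm_adjust(p) == pytest.approx(expected, rel=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stats.holm_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            stats.holm_adjust([0.5, 1.2])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=15))
    def test_bounds_property(self, p):
        out = stats.holm_adjust(p)
        p = np.asarray(p)
        assert (out >= p - 1e-15).all()
        assert (out <= np.minimum(1.0, len(p) * p) + 1e-12).all()
        # restores input order: adjusted values sorted like inputs
        assert (np.diff(out[np.argsort(p, kind="stable")]) >= -1e-15).all()


def _dataset(rng, groups=("a", "b"), n=(4, 5), q=3, shift=0.0):
    data = {}
    for lab in groups:
        Y = rng.normal(size=(n[0], q)) + shift
        X = rng.normal(size=(n[1], q))
        data[lab] = (Y, X)
    return stats.StatDataset(
        [(i, i + 10) for i in range(1, q + 1)], data, list(groups)
    )


class TestRunAnalyses:
    def test_all_identical_data_p_one(self):
        Y = np.ones((4, 2))
        X = np.ones((5, 2))
        ds = stats.StatDataset([(1, 2), (3, 4)], {"g": (Y, X)}, ["g"])
        table = stats.run_global_analysis(ds, n_perm=50, seed=0)
        assert table.raw_p.iloc[0] == 1.0

    def test_too_small_group_skipped_with_warning(self, rng):
        ds = _dataset(rng)
        ds.groups["empty"] = (np.empty((0, 3)), rng.normal(size=(3, 3)))
        ds.group_order.append("empty")
        with pytest.warns(UserWarning, match="skipped"):
            table = stats.run_global_analysis(ds, n_perm=50, seed=1)
        assert "empty" not in set(table.group)

    def test_adjusted_ge_raw(self, rng):
        table = stats.run_global_analysis(_dataset(rng), n_perm=200, seed=2)
        assert (table.adj_p >= table.raw_p - 1e-15).all()

    def test_local_q1_holm_identity(self, rng):
        ds = _dataset(rng, q=1)
        table = stats.run_local_analysis(ds, "a", n_perm=200, seed=3)
        assert table.adj_p.iloc[0] == pytest.approx(table.raw_p.iloc[0])

    def test_local_detects_large_shift(self, rng):
        ds = _dataset(rng, n=(8, 8), q=4)
        Y, X = ds.groups["a"]
        Y[:, 2] += 50.0  # huge effect on the third link only
        table = stats.run_local_analysis(ds, "a", n_perm=999, seed=4)
        assert tuple(table.iloc[0][["node_i", "node_j"]]) == (3, 13)
        assert table.significant.iloc[0]

    def test_local_null_rate(self, rng):
        hits = []
        for k in range(30):
            ds = _dataset(rng, n=(6, 6), q=5)
            t = stats.run_local_analysis(ds, "a", n_perm=199, seed=k)
            hits.extend(t.raw_p < 0.05)
        assert np.mean(hits) < 0.12
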