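from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hetshare.sharing import (
    bh_adjust,
    build_maf_pairs,
    maf_diff_vs_age,
    partition_permutation_test,
    partition_test_by_region,
    pearson_r_perm,
    shared_fraction,
    sharing_fisher,
    sharing_table,
    subsample_correlation_test,
)

TABLE1 = [[115, 21], [95, 260]]
TABLE2 = [[6, 11], [157, 51]]


def fisher_oracle(table):
    """Full hypergeometric enumeration: two-sided p = sum of probabilities
    of all same-margin tables no more probable than the observed one."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d

    def prob(k):
        return (comb(c1, k) * comb(n - c1, r1 - k)) / comb(n, r1)

    p_obs = prob(a)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    return sum(prob(k) for k in range(lo, hi + 1)
               if prob(k) <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_table1_significant(self):
        assert sharing_fisher(TABLE1) < 0.001

    def test_table2_value_range(self):
        p = sharing_fisher(TABLE2)
        assert 5e-4 < p < 1e-3
        assert p == pytest.approx(fisher_oracle(TABLE2), rel=1e-6)

    def test_symmetric_table(self):
        assert sharing_fisher([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_zero_margin_convention(self):
        assert sharing_fisher([[0, 0], [3, 5]]) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            sharing_fisher([[1, -1], [2, 3]])

    def test_enumeration_oracle_exhaustive_small_margins(self):
        """Agreement with the enumeration oracle for all tables with
        every cell <= 6 (margins <= 12)."""
        for a in range(7):
            for b in range(7):
                for c in range(7):
                    for d in range(7):
                        tab = [[a, b], [c, d]]
                        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                            continue
                        assert sharing_fisher(tab) == pytest.approx(
                            fisher_oracle(tab), abs=1e-9), tab


class TestSharedFraction:
    def test_table1_control(self):
        assert shared_fraction(TABLE1, 0) == pytest.approx(100 * 115 / 210)
        assert round(shared_fraction(TABLE1, 0)) == 55

    def test_table1_noncontrol(self):
        assert round(shared_fraction(TABLE1, 1), 1) == 7.5

    def test_all_shared(self):
        assert shared_fraction([[5, 2], [0, 0]], 0) == 100.0

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            shared_fraction([[0, 1], [0, 1]], 0)

    def test_margin_conservation(self):
        """Shared counts recovered from the two category fractions equal
        the table's shared margin."""
        tab = np.array(TABLE1, dtype=float)
        n0, n1 = tab[:, 0].sum(), tab[:, 1].sum()
        total_shared = (shared_fraction(tab, 0) / 100 * n0
                        + shared_fraction(tab, 1) / 100 * n1)
        assert total_shared == pytest.approx(tab[0].sum())


class TestPearsonPerm:
    def test_identical_vectors(self):
        x = np.arange(10.0)
        res = pearson_r_perm(x, x, n_perm=50, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_perm == pytest.approx(1 / 51)

    def test_negated_vector(self):
        x = np.arange(10.0)
        res = pearson_r_perm(x, -x, n_perm=50, seed=0)
        assert res.r == pytest.approx(-1.0)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            pearson_r_perm(np.ones(5), np.arange(5.0))

    def test_too_short(self):
        with pytest.raises(ValueError):
            pearson_r_perm([1, 2], [3, 4])

    def test_reproducible(self):
        rng = np.random.default_rng(1)
        x, y = rng.random(30), rng.random(30)
        a = pearson_r_perm(x, y, n_perm=99, seed=7)
        b = pearson_r_perm(x, y, n_perm=99, seed=7)
        assert a == b

    def test_null_uniformity(self):
        """Under independence, P(p <= alpha) stays near alpha."""
        rng = np.random.default_rng(2)
        n_perm, n_sim = 79, 250
        ps = []
        for i in range(n_sim):
            x, y = rng.random(40), rng.random(40)
            ps.append(pearson_r_perm(x, y, n_perm=n_perm, seed=1_000 + i).p_perm)
        ps = np.array(ps)
        for alpha in (0.05, 0.2):
            rate = np.mean(ps <= alpha)
            assert rate <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / n_sim)


class TestBhAdjust:
    def test_single(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_all_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_order_preserved(self):
        p = [0.04, 0.01, 0.03, 0.02]
        adj = bh_adjust(p)
        assert adj[1] == min(adj)
        np.testing.assert_allclose(sorted(adj), bh_adjust(sorted(p)))

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_properties(self, p):
        adj = bh_adjust(p)
        assert ((adj >= np.asarray(p) - 1e-12) | (np.asarray(p) > 1)).all()
        assert (adj <= 1.0 + 1e-12).all()
        # monotone: larger raw p never gets smaller adjusted p
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


def _pairs_frame(x, y, region=None, pos=None, shared=True, individual=None):
    n = len(x)
    return pd.DataFrame({
        "individual": individual if individual is not None else
            [f"I{i}" for i in range(n)],
        "pos": pos if pos is not None else np.arange(1, n + 1),
        "maf_a": x, "maf_b": y,
        "shared": shared if np.iterable(shared) else [shared] * n,
        "region": region if region is not None else ["control"] * n,
        "dloop": [False] * n,
    })


class TestPartitionTest:
    def test_degenerate_partition(self):
        rng = np.random.default_rng(0)
        pairs = _pairs_frame(rng.random(10), rng.random(10))
        with pytest.raises(ValueError):
            partition_permutation_test(pairs, 10)
        with pytest.raises(ValueError):
            partition_permutation_test(pairs, 0)

    def test_null_uniformity(self):
        rng = np.random.default_rng(3)
        ps = []
        for i in range(120):
            x = rng.random(60)
            y = x + rng.normal(0, 0.3, 60)
            pairs = _pairs_frame(x, y)
            ps.append(partition_permutation_test(pairs, 25, n_perm=79,
                                                 seed=i)["p"])
        rate = np.mean(np.array(ps) <= 0.05)
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 120)

    def test_detects_planted_difference(self):
        rng = np.random.default_rng(4)
        x1 = rng.random(80)
        y1 = x1 + rng.normal(0, 0.02, 80)  # tight correlation
        x2 = rng.random(80)
        y2 = rng.random(80)  # no correlation
        pairs = _pairs_frame(np.r_[x1, x2], np.r_[y1, y2],
                             region=["control"] * 80 + ["noncontrol"] * 80)
        res = partition_test_by_region(pairs, n_perm=199, seed=0)
        assert res["p"] <= 0.01
        assert res["delta_r"] > 0.5


class TestSubsampleTest:
    def test_target_is_population(self):
        rng = np.random.default_rng(5)
        x = rng.random(50)
        y = x + rng.normal(0, 0.1, 50)
        pairs = _pairs_frame(x, y, pos=np.arange(1, 51))
        res = subsample_correlation_test(pairs, set(range(1, 51)),
                                         n_perm=199, seed=1)
        # every subsample is the full population: r identical, p = 1
        assert np.allclose(res["null_r"], res["r_target"])
        assert res["p"] == pytest.approx(1.0)

    def test_random_target_p_moderate(self):
        rng = np.random.default_rng(6)
        x = rng.random(100)
        y = x + rng.normal(0, 0.1, 100)
        pairs = _pairs_frame(x, y, pos=np.arange(1, 101))
        res = subsample_correlation_test(pairs, set(range(1, 31)),
                                         n_perm=199, seed=2)
        assert 0.02 < res["p"] < 0.999
        assert res["n_target"] == 30

    def test_unknown_sites_error(self):
        pairs = _pairs_frame(np.arange(5.0), np.arange(5.0))
        with pytest.raises(ValueError):
            subsample_correlation_test(pairs, {999})


class TestMafDiffVsAge:
    def test_requires_shared_pairs(self):
        pairs = _pairs_frame(np.arange(5.0), np.arange(5.0), shared=False)
        with pytest.raises(ValueError):
            maf_diff_vs_age(pairs, pd.Series(dtype=float))

    def test_null_age_independence(self):
        rng = np.random.default_rng(7)
        n = 60
        x = rng.random(n) * 0.3
        y = x + rng.normal(0, 0.02, n)
        inds = [f"I{i}" for i in range(n)]
        ages = pd.Series(rng.integers(24, 95, n).astype(float), index=inds)
        pairs = _pairs_frame(x, y, individual=inds)
        out = maf_diff_vs_age(pairs, ages, n_perm=199, seed=0)
        res = out["per_region"]["control"]
        assert abs(res.r) < 0.5
        assert res.p_perm > 0.01

    def test_detects_age_dependent_jitter(self):
        rng = np.random.default_rng(8)
        n = 120
        inds = [f"I{i}" for i in range(n)]
        ages = rng.integers(24, 95, n).astype(float)
        x = rng.random(n) * 0.3 + 0.05
        y = x + rng.normal(0, 1e-4 + 0.004 * (ages - 24), n)
        pairs = _pairs_frame(x, y, individual=inds)
        out = maf_diff_vs_age(pairs, pd.Series(ages, index=inds),
                              n_perm=199, seed=0)
        res = out["per_region"]["control"]
        assert res.r > 0.2
        assert res.p_perm < 0.05

    def test_per_site_requires_min_individuals(self):
        rng = np.random.default_rng(9)
        n = 30
        inds = [f"I{i}" for i in range(n)]
        ages = pd.Series(rng.integers(24, 95, n).astype(float), index=inds)
        pairs = _pairs_frame(rng.random(n), rng.random(n), individual=inds,
                             pos=[72] * 25 + [60] * 5)
        out = maf_diff_vs_age(pairs, ages, n_perm=49, seed=0,
                              min_individuals_per_site=20)
        assert set(out["per_site"]) == {72}


class TestBuildMafPairs:
    def test_pairs_match_truth_sharing(self, small_cohort, small_calls):
        pairs = build_maf_pairs(small_calls, small_cohort, "liver1", "liver2")
        passed = small_calls.passed()
        liver = passed[passed["tissue"].isin(["liver1", "liver2"])]
        keys = {(r.individual, r.pos) for r in liver.itertuples()}
        assert {(r.individual, r.pos) for r in pairs.itertuples()} == keys
        # shared flag means called in both tissues
        for r in pairs.itertuples():
            tissues = set(liver[(liver["individual"] == r.individual)
                                & (liver["pos"] == r.pos)]["tissue"])
            assert r.shared == (tissues == {"liver1", "liver2"})

    def test_uncalled_side_gets_raw_maf(self, small_cohort, small_calls):
        pairs = build_maf_pairs(small_calls, small_cohort, "liver1", "liver2")
        unshared = pairs[~pairs["shared"]]
        assert len(unshared) > 0
        # raw MAFs are valid fractions
        assert unshared[["maf_a", "maf_b"]].min().min() >= 0.0
        assert unshared[["maf_a", "maf_b"]].max().max() <= 1.0

    def test_empty_calls_empty_pairs(self, small_cohort, small_calls):
        empty = small_calls
        import copy

        res = copy.copy(empty)
        res.calls = empty.calls.iloc[0:0]
        pairs = build_maf_pairs(res, small_cohort, "liver1", "liver2")
        assert pairs.empty

    def test_sharing_table_margins(self, small_cohort, small_calls):
        pairs = build_maf_pairs(small_calls, small_cohort, "liver1", "liver2")
        tab = sharing_table(pairs)
        assert tab.sum() == len(pairs[pairs["region"].isin(
            ["control", "noncontrol"])])
        assert tab[0].sum() == int(pairs["shared"].sum())
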