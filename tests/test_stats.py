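import math

import numpy as np
import pytest
from scipy import stats as sps

from hrdbench import (
    OverlapSamples,
    bonferroni_adjust,
    overlap_z_test,
    pairwise_fisher,
    proportion_ci,
    spearman_corr,
)


class TestProportionCi:
    @pytest.mark.parametrize(
        "k, n, pct, lo, hi",
        [
            # published Table-1 strata, percent to one decimal
            (5, 34, 14.7, 5.5, 31.8),
            (69, 76, 90.8, 81.4, 95.9),
            (29, 34, 85.3, 68.2, 94.5),
            (41, 46, 89.1, 75.6, 95.9),
            (20, 71, 28.2, 18.4, 40.3),
            (51, 71, 71.8, 59.7, 81.6),
        ],
    )
    def test_wilson_cc_reproduces_published_intervals(self, k, n, pct, lo, hi):
        est = proportion_ci(k, n)
        assert round(100 * est.proportion, 1) == pct
        assert round(100 * est.lower, 1) == lo
        assert round(100 * est.upper, 1) == hi

    def test_zero_successes_lower_bound_zero(self):
        est = proportion_ci(0, 10)
        assert est.lower == 0.0 and est.upper > 0

    @pytest.mark.parametrize("k, n", [(3, 12), (7, 30), (20, 71)])
    def test_mirror_symmetry(self, k, n):
        a = proportion_ci(k, n)
        b = proportion_ci(n - k, n)
        assert a.lower == pytest.approx(1 - b.upper, abs=1e-12)
        assert a.upper == pytest.approx(1 - b.lower, abs=1e-12)

    def test_bounds_bracket_and_width_shrinks(self):
        small = proportion_ci(5, 34)
        large = proportion_ci(50, 340)
        for est in (small, large):
            assert 0 <= est.lower <= est.proportion <= est.upper <= 1
        assert (large.upper - large.lower) < (small.upper - small.lower)

    def test_alternative_methods(self):
        wilson = proportion_ci(5, 34, method="wilson")
        cp = proportion_ci(5, 34, method="clopper_pearson")
        cc = proportion_ci(5, 34)
        # plain Wilson is narrower than its continuity-corrected version;
        # Clopper-Pearson is conservative (at least as wide as Wilson)
        assert (wilson.upper - wilson.lower) < (cc.upper - cc.lower)
        assert (cp.upper - cp.lower) > (wilson.upper - wilson.lower)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            proportion_ci(1, 0)
        with pytest.raises(ValueError):
            proportion_ci(5, 4)
        with pytest.raises(ValueError):
            proportion_ci(1, 10, method="jeffreys")


def _perm_oracle_z(paired, only_a, only_b, z_obs, reps=100_000, seed=123):
    """Permutation null: swap outcomes within pairs, shuffle unpaired pool."""
    rng = np.random.default_rng(seed)
    pa = np.array([a for a, _ in paired])
    pb = np.array([b for _, b in paired])
    c = pa.size
    un = np.array(list(only_a) + list(only_b))
    n_oa = len(only_a)

    swap = rng.random((reps, c)) < 0.5
    PA = np.where(swap, pb, pa)
    PB = np.where(swap, pa, pb)
    UN = np.tile(un, (reps, 1))
    order = np.argsort(rng.random(UN.shape), axis=1)
    UN = np.take_along_axis(UN, order, axis=1)
    OA, OB = UN[:, :n_oa], UN[:, n_oa:]

    na = c + OA.shape[1]
    nb = c + OB.shape[1]
    xa = PA.sum(1) + OA.sum(1)
    xb = PB.sum(1) + OB.sum(1)
    pooled = (xa + xb) / (na + nb)
    a11 = (PA & PB).sum(1)
    a10 = (PA & ~PB).sum(1)
    a01 = (~PA & PB).sum(1)
    a00 = c - a11 - a10 - a01
    m = (a11 + a10) * (a01 + a00) * (a11 + a01) * (a10 + a00)
    phi = np.where(m > 0, (a11 * a00 - a10 * a01) / np.sqrt(np.where(m > 0, m, 1)), 0.0)
    var = pooled * (1 - pooled) * (1 / na + 1 / nb - 2 * phi * c / (na * nb))
    z = np.where(var > 0, (xa / na - xb / nb) / np.sqrt(np.where(var > 0, var, 1)), 0.0)
    return float(np.mean(z >= z_obs - 1e-12))


class TestOverlapZTest:
    def test_identical_paired_outcomes_degenerate(self):
        data = OverlapSamples([(True, True), (False, False)], [], [])
        z, p = overlap_z_test(data, "greater")
        assert z == 0.0 and p == 0.5

    def test_no_paired_reduces_to_classical_two_proportion_z(self):
        from statsmodels.stats.proportion import proportions_ztest

        only_a = [True] * 12 + [False] * 8
        only_b = [True] * 5 + [False] * 15
        z, p = overlap_z_test(OverlapSamples([], only_a, only_b), "greater")
        z_ref, p_ref = proportions_ztest([12, 5], [20, 20], alternative="larger")
        assert z == pytest.approx(z_ref)
        assert p == pytest.approx(p_ref)

    def test_p_close_to_permutation_oracle(self):
        """Frozen 40-paired + 10/10-unpaired instance vs 1e5-rep permutation."""
        rng = np.random.default_rng(42)
        pa = rng.random(40) < 0.55
        pb = (rng.random(40) < 0.75) & pa | (rng.random(40) < 0.3)
        paired = list(zip(pa.tolist(), pb.tolist()))
        only_a = (rng.random(10) < 0.6).tolist()
        only_b = (rng.random(10) < 0.4).tolist()
        z, p = overlap_z_test(OverlapSamples(paired, only_a, only_b), "greater")
        p_perm = _perm_oracle_z(paired, only_a, only_b, z)
        # the statistic is asymptotically normal; at n=60 the discrete
        # permutation null differs from the normal tail by a few percent
        assert p == pytest.approx(p_perm, abs=0.06)

    def test_larger_instance_tighter_agreement(self):
        rng = np.random.default_rng(5)
        pa = rng.random(80) < 0.5
        pb = (pa & (rng.random(80) < 0.7)) | (~pa & (rng.random(80) < 0.35))
        paired = list(zip(pa.tolist(), pb.tolist()))
        only_a = (rng.random(30) < 0.55).tolist()
        only_b = (rng.random(30) < 0.45).tolist()
        z, p = overlap_z_test(OverlapSamples(paired, only_a, only_b), "greater")
        p_perm = _perm_oracle_z(paired, only_a, only_b, z)
        assert p == pytest.approx(p_perm, abs=0.02)

    def test_alternatives(self):
        data = OverlapSamples([(True, False)] * 6 + [(False, False)] * 6, [], [])
        z, p_g = overlap_z_test(data, "greater")
        _, p_l = overlap_z_test(data, "less")
        _, p_2 = overlap_z_test(data, "two-sided")
        assert z > 0
        assert p_g + p_l == pytest.approx(1.0)
        assert p_2 == pytest.approx(2 * p_g)

    def test_empty_everything_rejected(self):
        with pytest.raises(ValueError):
            OverlapSamples([], [], [])


def fisher_enumeration(table, alternative="less"):
    """Hypergeometric tail by direct enumeration over all feasible tables."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    rv = sps.hypergeom(n, col1, row1)
    support = range(max(0, row1 + col1 - n), min(row1, col1) + 1)
    if alternative == "less":
        return sum(rv.pmf(x) for x in support if x <= a)
    if alternative == "greater":
        return sum(rv.pmf(x) for x in support if x >= a)
    p_obs = rv.pmf(a)
    return sum(rv.pmf(x) for x in support if rv.pmf(x) <= p_obs * (1 + 1e-9))


class TestPairwiseFisher:
    def test_identical_groups_all_p_one(self):
        res = pairwise_fisher({"a": (5, 10), "b": (5, 10)}, alternative="two-sided")
        assert res[("a", "b")]["p_raw"] == pytest.approx(1.0)

    def test_extreme_table_closed_form(self):
        res = pairwise_fisher({"a": (0, 10), "b": (10, 0)}, alternative="less")
        assert res[("a", "b")]["p_raw"] == pytest.approx(1 / math.comb(20, 10))

    def test_published_breast_vs_pancreas_contrast(self):
        """11/76 unexplained in breast vs 20/51 in pancreas, one-sided,
        Bonferroni x3 (three cancer-type pairs) ~ 0.0375."""
        groups = {"breast": (11, 76), "ovary": (11, 30), "pancreas": (20, 51)}
        res = pairwise_fisher(groups, alternative="less")
        assert res[("breast", "pancreas")]["p_adjusted"] == pytest.approx(
            0.0375, abs=0.001
        )

    @pytest.mark.parametrize("seed", range(4))
    @pytest.mark.parametrize("alternative", ["less", "greater", "two-sided"])
    def test_matches_hypergeometric_enumeration(self, seed, alternative):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(0, 50, 4)  # n <= 200
        res = pairwise_fisher(
            {"g1": (int(a), int(b)), "g2": (int(c), int(d))},
            alternative=alternative,
        )
        expected = fisher_enumeration([[a, b], [c, d]], alternative)
        assert res[("g1", "g2")]["p_raw"] == pytest.approx(expected, rel=1e-6)

    def test_zero_total_group_undefined(self):
        res = pairwise_fisher({"a": (0, 0), "b": (3, 4)})
        assert math.isnan(res[("a", "b")]["p_raw"])

    def test_adjustment_uses_number_of_pairs(self):
        groups = {"a": (1, 9), "b": (5, 5), "c": (9, 1)}
        res = pairwise_fisher(groups, alternative="less")
        for v in res.values():
            assert v["p_adjusted"] == pytest.approx(min(1.0, v["p_raw"] * 3))


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman_corr(x, x) == pytest.approx(1.0)
        assert spearman_corr(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_tied_instance_equals_pearson_of_midranks(self, rng):
        x = rng.choice([0.1, 0.2, 0.5], size=15)
        y = rng.choice([0.3, 0.4, 0.9], size=15)
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman_corr(x, y) == pytest.approx(expected)

    def test_constant_vector_is_nan(self):
        assert math.isnan(spearman_corr([1, 1, 1], [1, 2, 3]))


class TestBonferroni:
    def test_examples(self):
        assert bonferroni_adjust([0.01, 0.04]) == [0.02, 0.08]
        assert bonferroni_adjust([0.6]) == [0.6]

    def test_never_decreases_and_caps(self, rng):
        ps = rng.random(10)
        adj = bonferroni_adjust(list(ps))
        assert all(a >= p for a, p in zip(adj, ps))
        assert all(a <= 1.0 for a in adj)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.2])
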