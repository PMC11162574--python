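import itertools
import math

import numpy as np
import pandas as pd
import pytest

from dupevol import cistrans, simulate
from dupevol.io import CountTable


def make_table(pm_a, pm_c, allo_an, allo_cn, pair_id="p1"):
    return CountTable(
        counts=pd.DataFrame(
            {
                "pm_a": [np.array(pm_a)],
                "pm_c": [np.array(pm_c)],
                "allo_an": [np.array(allo_an)],
                "allo_cn": [np.array(allo_cn)],
            },
            index=pd.Index([pair_id], name="pair_id"),
        )
    )


class TestComputeRatios:
    def test_balanced_counts_give_zero_ratios(self):
        table = make_table([100, 100], [100, 100], [100, 100], [100, 100])
        (rp,), _ = cistrans.compute_ratios(table, pseudocount=0.0)
        assert rp.a == 0.0 and rp.b == 0.0 and rp.trans == 0.0

    def test_hand_computed_log2_ratios(self):
        # A = log2(200/100) = 1 in both generations -> trans = 0
        table = make_table([200], [100], [200], [100])
        (rp,), _ = cistrans.compute_ratios(table, pseudocount=0.0,
                                           scale_libraries=False)
        assert rp.a == pytest.approx(1.0) and rp.b == pytest.approx(1.0)
        assert rp.trans == pytest.approx(0.0)

    def test_progeny_only_divergence_gives_negative_trans(self):
        table = make_table([100], [100], [200], [100])
        (rp,), _ = cistrans.compute_ratios(table, pseudocount=0.0,
                                           scale_libraries=False)
        assert rp.a == pytest.approx(0.0)
        assert rp.b == pytest.approx(1.0)
        assert rp.trans == pytest.approx(-1.0)

    def test_all_zero_side_flagged_untestable(self):
        table = make_table([0, 0], [0, 0], [5, 5], [5, 5])
        pairs, untestable = cistrans.compute_ratios(table)
        assert pairs == [] and untestable == ["p1"]

    def test_library_scaling_leaves_ratios_unchanged(self):
        # within-sample ratios are depth-invariant; scaling only rescales counts
        t = make_table([300, 300], [100, 100], [60, 60], [20, 20])
        (r1,), _ = cistrans.compute_ratios(t, pseudocount=0.0, scale_libraries=True)
        (r2,), _ = cistrans.compute_ratios(t, pseudocount=0.0, scale_libraries=False)
        assert r1.a == pytest.approx(r2.a) and r1.b == pytest.approx(r2.b)


class TestDivergenceTest:
    def test_balanced_pool_is_nonsignificant(self):
        assert cistrans.test_divergence([25, 25], [25, 25]) == pytest.approx(1.0)

    def test_one_sided_extreme_matches_closed_form(self):
        # P = 2 * 0.5^10 for 10 successes out of 10 trials
        assert cistrans.test_divergence([10], [0]) == pytest.approx(2 * 0.5**10)

    def test_zero_total_untestable(self):
        assert math.isnan(cistrans.test_divergence([0], [0]))


def welch_oracle(x, y):
    """Welch statistic and p-value from the textbook formulas."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    from scipy.stats import t as tdist

    return t, 2 * tdist.sf(abs(t), df)


class TestTransTest:
    def test_identical_ratio_vectors_give_p_one(self):
        assert cistrans.test_trans([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == 1.0

    def test_matches_welch_oracle(self, rng):
        _, p0 = welch_oracle([0, 0, 0.1], [2, 2, 2.1])
        assert cistrans.test_trans([0, 0, 0.1], [2, 2, 2.1]) == pytest.approx(
            p0, abs=1e-10
        )
        for _ in range(500):
            x = rng.normal(size=rng.integers(2, 8))
            y = rng.normal(size=rng.integers(2, 8))
            _, p0 = welch_oracle(x, y)
            assert abs(cistrans.test_trans(x, y) - p0) < 1e-10

    def test_single_replicate_untestable(self):
        assert math.isnan(cistrans.test_trans([1.0], [1.0, 2.0]))


def bh_oracle(p):
    """Step-up BH written out longhand."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


class TestBhFdr:
    def test_hand_computed_example(self):
        q = cistrans.bh_fdr([0.005, 0.011, 0.02, 0.04])
        np.testing.assert_allclose(q, [0.02, 0.022, 0.02 + 1 / 150, 0.04], atol=1e-12)

    def test_all_ones_stay_one_and_singleton_identity(self):
        assert cistrans.bh_fdr([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]
        assert cistrans.bh_fdr([0.03]).tolist() == [0.03]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cistrans.bh_fdr([0.5, 1.5])

    def test_matches_stepup_oracle_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(cistrans.bh_fdr(p), bh_oracle(list(p)),
                                       atol=1e-10)

    def test_monotone_in_inputs(self, rng):
        for _ in range(200):
            p = rng.uniform(size=10)
            q = cistrans.bh_fdr(p)
            i = rng.integers(10)
            p2 = p.copy()
            p2[i] *= rng.uniform()
            q2 = cistrans.bh_fdr(p2)
            assert q2[i] <= q[i] + 1e-12


class TestAssignCategory:
    @pytest.mark.parametrize(
        "flags, expected",
        [
            ((False, False, False), "VI conserved"),
            ((True, True, False), "I cis-only"),
            ((True, False, True), "II trans-only"),
            ((False, True, True), "V compensatory"),
        ],
    )
    def test_sign_free_branches(self, flags, expected):
        assert cistrans.assign_category(*flags, sign_b=1, sign_trans=1) == expected

    def test_sign_dependent_branches(self):
        assert (
            cistrans.assign_category(True, True, True, sign_b=1, sign_trans=1)
            == "III cis+trans enhancing"
        )
        assert (
            cistrans.assign_category(True, True, True, sign_b=1, sign_trans=-1)
            == "IV cis*trans opposing"
        )

    def test_partition_over_all_flag_sign_combinations(self):
        """Every (sig_a, sig_b, sig_ab, sign_b, sign_trans) combination maps
        to exactly one of the seven categories."""
        seen = set()
        for sig_a, sig_b, sig_ab in itertools.product([False, True], repeat=3):
            for sign_b, sign_trans in itertools.product([-1, 1], repeat=2):
                cat = cistrans.assign_category(sig_a, sig_b, sig_ab, sign_b, sign_trans)
                assert cat in cistrans.CATEGORIES
                seen.add(cat)
        assert seen == set(cistrans.CATEGORIES)


def chi2_oracle(table):
    """Pearson chi-squared statistic from the definitional formula."""
    table = np.asarray(table, float)
    total = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            exp = table[i].sum() * table[:, j].sum() / total
            stat += (table[i, j] - exp) ** 2 / exp
    return stat


class TestCategorySummary:
    def _calls(self, categories):
        return [
            cistrans.CategoryCall(f"p{i}", 0, 0, 0, 1, 1, 1, c)
            for i, c in enumerate(categories)
        ]

    def test_single_category_proportion_one(self):
        summary = cistrans.category_summary(self._calls(["VI conserved"] * 5))
        row = summary[(summary.tissue == "pooled") & (summary.category == "VI conserved")]
        assert row["proportion"].iloc[0] == 1.0

    def test_identical_call_sets_not_distinguishable(self):
        calls = self._calls(["VI conserved"] * 10 + ["I cis-only"] * 5)
        stat, p = cistrans.compare_call_sets(calls, calls)
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_chi_squared_matches_definitional_oracle(self):
        calls_x = self._calls(["VI conserved"] * 10 + ["I cis-only"] * 20)
        calls_y = self._calls(["VI conserved"] * 20 + ["I cis-only"] * 10)
        stat, _ = cistrans.compare_call_sets(calls_x, calls_y)
        assert stat == pytest.approx(chi2_oracle([[10, 20], [20, 10]]), abs=1e-10)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cistrans.category_summary([])


class TestPlantedRecovery:
    def test_strong_planted_categories_recovered(self):
        """Planted cis/trans effects are recovered at high rate for the
        cleanly-identified categories (cis-only, trans-only, enhancing,
        conserved) under overdispersed counts with 3 replicates."""
        cfg = simulate.CountSimConfig(seed=2024, n_pairs=600)
        table, truth = simulate.simulate_count_dataset(cfg)
        calls = cistrans.call_categories(table)
        pred = pd.Series({c.pair_id: c.category for c in calls})
        joined = truth.join(pred.rename("pred"))
        for cat in ("I cis-only", "II trans-only", "III cis+trans enhancing",
                    "VI conserved"):
            sub = joined[joined.category == cat]
            assert (sub.pred == cat).mean() >= 0.9, cat
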