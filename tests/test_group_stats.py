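"""pH grouping, descriptive stats, Kruskal-Wallis and Dunn-Sidak."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from neoecg.group_stats import (
    DunnComparison, assign_group, describe, dunn_sidak, kruskal_wallis,
    run_feature_tests,
)


class TestAssignGroup:
    @pytest.mark.parametrize("ph,expected", [
        (7.10, "acidosis"), (7.30, "normal"), (7.50, "alkalosis"),
        (7.20, "normal"), (7.45, "normal"),  # boundaries fall to normal
        (6.5, "acidosis"), (8.0, "alkalosis"),
    ])
    def test_partition(self, ph, expected):
        assert assign_group(ph) == expected

    def test_out_of_bounds_rejected(self):
        for ph in (6.4, 8.1):
            with pytest.raises(ValueError):
                assign_group(ph)

    @given(ph=st.floats(6.5, 8.0))
    def test_every_plausible_ph_gets_exactly_one_group(self, ph):
        assert assign_group(ph) in ("acidosis", "normal", "alkalosis")


class TestDescribe:
    def test_median_and_interpolated_iqr(self):
        out = describe([1, 2, 3, 4, 5], ["g"] * 5).set_index("group")
        assert out.loc["g", "median"] == 3
        assert out.loc["g", "q1"] == 2 and out.loc["g", "q3"] == 4
        assert out.loc["g", "iqr"] == 2

    def test_single_value_group(self):
        out = describe([7.0], ["g"]).set_index("group")
        assert out.loc["g", "median"] == 7.0 and out.loc["g", "iqr"] == 0.0

    def test_constant_values_scale_without_error(self):
        out = describe([2.0, 2.0, 2.0], ["a", "a", "b"])
        assert set(out["n"]) == {1, 2}
        assert np.all(out.attrs["scaled"]["scaled"] == 0.5)

    def test_empty_group_reported_with_n_zero(self):
        out = describe([1.0, 2.0], ["acidosis", "acidosis"],
                       groups=["acidosis", "normal", "alkalosis"]).set_index("group")
        assert out.loc["normal", "n"] == 0
        assert np.isnan(out.loc["normal", "median"])


class TestKruskalWallis:
    def test_separated_groups_hand_value(self):
        res = kruskal_wallis([1, 2, 3, 4, 5, 6, 7, 8, 9],
                             ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert res.h == pytest.approx(7.2, abs=1e-12)
        assert res.df == 2

    def test_balanced_ranks_give_zero(self):
        res = kruskal_wallis([1, 6, 8, 2, 4, 9, 3, 5, 7],
                             ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert res.h == pytest.approx(0.0, abs=1e-12)

    def test_interleaved_groups_hand_value(self):
        res = kruskal_wallis([1, 4, 7, 2, 5, 8, 3, 6, 9],
                             ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert res.h == pytest.approx(0.8, abs=1e-12)

    def test_all_identical_values(self):
        res = kruskal_wallis([5.0] * 9, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert res.h == 0.0 and res.p == 1.0 and res.tie_correction == 0.0

    def test_rank_sum_invariant(self):
        rng = np.random.default_rng(0)
        v = rng.integers(0, 5, size=30).astype(float)  # plenty of ties
        labels = rng.choice(["a", "b", "c"], size=30)
        res = kruskal_wallis(v, labels)
        total = sum(g["n"] * g["mean_rank"] for g in res.groups)
        n = len(v)
        assert total == pytest.approx(n * (n + 1) / 2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.integers(0, 8, size=n).astype(float) for n in (6, 9, 5)]
        labels = ["a"] * 6 + ["b"] * 9 + ["c"] * 5
        res = kruskal_wallis(np.concatenate(groups), labels)
        ref = stats.kruskal(*groups)
        assert res.h == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_exhaustive_three_group_partitions_match_brute_force(self):
        """Every 3-group partition of 7 distinct values agrees with a naive
        rank computation and with scipy."""
        values = np.array([3.1, -1.0, 0.0, 2.5, 7.7, 5.2, 4.4])
        n = 7
        checked = 0
        for assignment in itertools.product(range(3), repeat=n):
            sizes = [assignment.count(g) for g in range(3)]
            if min(sizes) == 0:
                continue
            labels = [f"g{a}" for a in assignment]
            res = kruskal_wallis(values, labels)
            # brute force: ranks by explicit sort, plain H formula
            order = np.argsort(values)
            ranks = np.empty(n)
            ranks[order] = np.arange(1, n + 1)
            h = 0.0
            for g in range(3):
                idx = [i for i in range(n) if assignment[i] == g]
                rbar = np.mean(ranks[idx])
                h += len(idx) * (rbar - (n + 1) / 2) ** 2
            h *= 12.0 / (n * (n + 1))
            assert res.h == pytest.approx(h, abs=1e-10)
            groups = [values[[i for i in range(n) if assignment[i] == g]]
                      for g in range(3)]
            assert res.h == pytest.approx(stats.kruskal(*groups).statistic, abs=1e-10)
            checked += 1
        assert checked == 3 ** 7 - 3 * 2 ** 7 + 3  # onto assignments

    @given(st.permutations(range(9)))
    def test_invariant_under_monotone_transform(self, perm):
        values = np.array(perm, dtype=float)
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        base = kruskal_wallis(values, labels)
        mono = kruskal_wallis(np.exp(values / 3.0), labels)
        assert mono.h == pytest.approx(base.h, abs=1e-9)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0, 2.0], ["a", "a"])


class TestDunnSidak:
    def test_two_group_hand_values(self):
        comps = dunn_sidak([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert len(comps) == 1
        c = comps[0]
        assert c.estimate == pytest.approx(-3.0, abs=1e-12)
        se = np.sqrt(6 * 7 / 12 * (1 / 3 + 1 / 3))
        assert se == pytest.approx(1.5275, abs=5e-5)
        assert c.z == pytest.approx(-1.9640, abs=5e-5)
        assert c.p_raw == pytest.approx(0.0495, abs=5e-4)
        # with one comparison the Sidak adjustment is the identity
        assert c.p_adj == pytest.approx(c.p_raw, abs=1e-12)

    def test_identical_multisets_are_null(self):
        comps = dunn_sidak([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        c = comps[0]
        assert c.estimate == 0.0
        assert c.p_adj == pytest.approx(1.0)
        assert c.lower == pytest.approx(-c.upper)
        assert not c.significant

    def test_tie_free_se_reduces_to_closed_form(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=12)
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        comps = dunn_sidak(v, labels)
        n = 12
        se = np.sqrt(n * (n + 1) / 12 * (1 / 4 + 1 / 4))
        for c in comps:
            width = (c.upper - c.lower) / 2
            z_crit = width / se
            # same critical value for every pair
            assert z_crit == pytest.approx((comps[0].upper - comps[0].lower) / 2 / se)

    @pytest.mark.parametrize("seed", range(20))
    def test_decision_interval_coherence(self, seed):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(3, 15, size=3)
        v = np.concatenate([rng.normal(loc=rng.uniform(-1, 1), size=s)
                            for s in sizes])
        labels = sum([[f"g{i}"] * s for i, s in enumerate(sizes)], [])
        for c in dunn_sidak(v, labels):
            assert c.significant == (c.p_adj < 0.05)
            assert c.significant == (c.lower > 0 or c.upper < 0)
            assert c.lower <= c.estimate <= c.upper


class TestRunFeatureTests:
    def _table(self, shift=0.0, n=(9, 83, 16), seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, size in zip(("acidosis", "normal", "alkalosis"), n):
            loc = shift if g == "acidosis" else 0.0
            for v in rng.normal(loc, 1.0, size):
                rows.append({"t_amplitude": v, "hr": rng.normal(), "group": g})
        return pd.DataFrame(rows)

    def test_posthoc_only_when_omnibus_significant(self):
        report = run_feature_tests(self._table(shift=3.0, seed=1),
                                   feature_columns=["t_amplitude", "hr"])
        assert report["features"]["t_amplitude"]["significant"]
        assert report["features"]["t_amplitude"]["pairs"]
        # post hoc is strictly conditional on the omnibus result
        for entry in report["features"].values():
            assert bool(entry["pairs"]) == entry["significant"]
        assert not report["features"]["hr"]["significant"]

    def test_force_posthoc_computes_all_pairs(self):
        report = run_feature_tests(self._table(), feature_columns=["hr"],
                                   force_posthoc=True)
        assert len(report["features"]["hr"]["pairs"]) == 3

    def test_single_group_input_skips_tests(self):
        df = self._table(n=(0, 10, 0))
        report = run_feature_tests(df, feature_columns=["t_amplitude"])
        assert "note" in report

    def test_missing_feature_column_warns_and_skips(self):
        df = self._table()
        df["t_amplitude"] = np.nan
        with pytest.warns(UserWarning, match="entirely missing"):
            report = run_feature_tests(df, feature_columns=["t_amplitude", "hr"])
        assert "t_amplitude" not in report["features"]
        assert "hr" in report["features"]
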