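"""Retailer-subset coverage analysis: proportions, differences, dispersion."""

import numpy as np
import pandas as pd
import pytest

from cpdtools import (
    coverage_differences,
    dispersion_summary,
    group_proportions,
    percentile_summary,
    rank_retailers,
    top_food_groups,
)
from cpdtools.coverage import default_subsets


def lines(rows):
    df = pd.DataFrame(rows, columns=["participant_id", "retailer_id", "group", "quantity"])
    df["quantity"] = df["quantity"].astype(int)
    return df


SIMPLE = lines(
    [("P1", "A", "bread", 1)] * 10
    + [("P1", "B", "milk", 1)] * 5
    + [("P2", "C", "bread", 1)] * 5
)


class TestRanking:
    def test_descending_with_id_tie_break(self):
        assert rank_retailers(SIMPLE) == ["A", "B", "C"]

    def test_single_retailer(self):
        assert rank_retailers(lines([("P1", "Z", "g", 1)])) == ["Z"]

    def test_permutation_invariant(self):
        shuffled = SIMPLE.sample(frac=1.0, random_state=3)
        assert rank_retailers(shuffled) == rank_retailers(SIMPLE)


class TestTopGroups:
    def test_frequency_order(self):
        assert top_food_groups(SIMPLE, k=2) == ["bread", "milk"]

    def test_fewer_groups_than_k_warns(self):
        with pytest.warns(UserWarning, match="fewer than"):
            out = top_food_groups(SIMPLE, k=20)
        assert out == ["bread", "milk"]

    def test_non_food_groups_excluded(self):
        out = top_food_groups(SIMPLE, k=5, is_food={"bread": True, "milk": False})
        assert out == ["bread"]


class TestGroupProportions:
    def test_single_retailer_loyalty_matches_full(self):
        df = lines([("P1", "A", "bread", 1)] * 3 + [("P1", "A", "milk", 1)])
        props, flag = group_proportions(df, "P1", ["A"], ["bread", "milk"])
        assert not flag
        assert props == pytest.approx([0.75, 0.25])

    def test_zero_subset_flagged(self):
        props, flag = group_proportions(SIMPLE, "P2", ["A"], ["bread"])
        assert flag and np.isnan(props).all()

    def test_unknown_retailer_raises(self):
        with pytest.raises(ValueError, match="unknown retailer"):
            group_proportions(SIMPLE, "P1", ["Q"], ["bread"])

    def test_brute_force_recount_on_fixture(self):
        rng = np.random.default_rng(4)
        rows = [
            ("P1", rng.choice(["A", "B"]), rng.choice(["g1", "g2", "g3"]), rng.integers(1, 4))
            for _ in range(20)
        ]
        df = lines(rows)
        props, _ = group_proportions(df, "P1", ["A"], ["g1", "g2"], weight="quantity")
        sub = df[df.retailer_id == "A"]
        denom = sub["quantity"].sum()
        for j, g in enumerate(["g1", "g2"]):
            assert props[j] == pytest.approx(
                sub.loc[sub.group == g, "quantity"].sum() / denom
            )


class TestCoverageDifferences:
    def test_full_subset_differences_exactly_zero(self):
        ranking = rank_retailers(SIMPLE)
        cov = coverage_differences(
            SIMPLE, ["bread", "milk"], subsets=[("cumulative", "all", ranking)]
        )
        assert (cov["pp_difference"] == 0.0).all()
        defined = cov["rel_difference_pct"].dropna()
        assert (defined == 0.0).all()

    def test_group_absent_from_subset_gives_minus_100(self):
        # tobacco only sold at retailer B; evaluate participant on A alone
        df = lines(
            [("P1", "A", "bread", 1)] * 8 + [("P1", "B", "tobacco", 1)] * 2
        )
        cov = coverage_differences(df, ["bread", "tobacco"], subsets=[("individual", "A", ["A"])])
        row = cov[(cov.participant_id == "P1") & (cov.group == "tobacco")].iloc[0]
        assert row["rel_difference_pct"] == -100.0

    def test_two_by_two_fixture_matches_hand_enumeration(self):
        df = lines(
            [("P1", "A", "g1", 1)] * 3 + [("P1", "B", "g2", 1)]
            + [("P2", "A", "g2", 1)] + [("P2", "B", "g1", 1)]
        )
        cov = coverage_differences(df, ["g1", "g2"], subsets=[("individual", "A", ["A"])])
        p1g1 = cov[(cov.participant_id == "P1") & (cov.group == "g1")].iloc[0]
        # P1 at A: 3/3 g1 vs full 3/4 -> pp = +25, rel = +33.33
        assert p1g1["pp_difference"] == pytest.approx(25.0)
        assert p1g1["rel_difference_pct"] == pytest.approx(100 * (1 - 0.75) / 0.75)
        p2g1 = cov[(cov.participant_id == "P2") & (cov.group == "g1")].iloc[0]
        # P2 at A: 0/1 g1 vs full 1/2 -> pp = -50, rel = -100
        assert p2g1["pp_difference"] == pytest.approx(-50.0)
        assert p2g1["rel_difference_pct"] == -100.0

    def test_zero_full_proportion_drops_relative_keeps_pp(self):
        df = lines([("P1", "A", "g1", 1)] * 4)
        cov = coverage_differences(df, ["g1", "g2"], subsets=[("individual", "A", ["A"])])
        g2 = cov[cov.group == "g2"].iloc[0]
        assert np.isnan(g2["rel_difference_pct"])
        assert g2["pp_difference"] == 0.0

    def test_relative_difference_bounded_below(self, small_enriched):
        cov = coverage_differences(
            small_enriched.line_table[small_enriched.line_table["group"] != ""],
            top_food_groups(small_enriched.line_table, 10),
        )
        defined = cov["rel_difference_pct"].dropna()
        assert (defined >= -100.0).all()


class TestDispersion:
    def test_full_set_sd_exactly_zero(self):
        ranking = rank_retailers(SIMPLE)
        cov = coverage_differences(SIMPLE, ["bread", "milk"])
        disp = dispersion_summary(cov)
        full = disp[
            (disp.subset_type == "cumulative")
            & (disp.subset_size == len(ranking))
            & (disp.group == "__pooled__")
        ]
        assert full["sd_pp"].iloc[0] == 0.0

    def test_single_participant_sd_missing(self):
        df = lines([("P1", "A", "g1", 1), ("P1", "B", "g1", 1)])
        cov = coverage_differences(df, ["g1"], subsets=[("individual", "A", ["A"])])
        disp = dispersion_summary(cov)
        assert disp[disp.group == "g1"]["sd_pp"].isna().all()


class TestPercentiles:
    def _cov(self, rels, size=1):
        return pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(len(rels))],
                "subset_type": "cumulative",
                "subset_label": f"top{size}",
                "subset_size": size,
                "group": "g1",
                "p_subset": 0.5,
                "p_full": 0.5,
                "pp_difference": 0.0,
                "rel_difference_pct": rels,
                "zero_subset_flag": False,
            }
        )

    def test_all_zero(self):
        out = percentile_summary(self._cov([0.0, 0.0, 0.0]), subset_sizes=[1])
        assert (out["rel_difference_pct"] == 0.0).all()

    def test_median_of_symmetric_triplet(self):
        out = percentile_summary(self._cov([-100.0, 0.0, 100.0]), percentiles=[50], subset_sizes=[1])
        assert out["rel_difference_pct"].iloc[0] == 0.0

    def test_matches_sort_oracle_on_25_values(self):
        rng = np.random.default_rng(9)
        vals = rng.uniform(-100, 100, 25)
        out = percentile_summary(self._cov(list(vals)), percentiles=[10, 50, 90], subset_sizes=[1])
        for pct, got in zip(out["percentile"], out["rel_difference_pct"]):
            # sort-based linear interpolation oracle
            s = np.sort(vals)
            h = (len(s) - 1) * pct / 100
            lo, hi = int(np.floor(h)), int(np.ceil(h))
            oracle = s[lo] + (h - lo) * (s[hi] - s[lo])
            assert got == pytest.approx(oracle)


def test_default_subsets_structure():
    subsets = default_subsets(["A", "B", "C"], n_individual=2)
    labels = [(t, l) for t, l, _ in subsets]
    assert ("individual", "A") in labels and ("individual", "B") in labels
    cumulative = [s for s in subsets if s[0] == "cumulative"]
    assert [len(s[2]) for s in cumulative] == [1, 2, 3]
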