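"""The synthetic cohort generator: determinism, truth structure, knobs."""

import numpy as np
import pandas as pd
import pytest

from cpdtools import CohortConfig, generate_catalog, generate_cohort, generate_receipts
from cpdtools.gtin import is_valid_gtin13
from cpdtools.synthetic import generate_databases, write_cohort


class TestCatalog:
    def test_deterministic_given_seed(self):
        cfg = CohortConfig(n_products=10, seed=1)
        p1, _ = generate_catalog(cfg)
        p2, _ = generate_catalog(cfg)
        pd.testing.assert_frame_equal(p1, p2)

    def test_all_gtins_pass_check_digit(self):
        cfg = CohortConfig(n_products=500, seed=2)
        products, _ = generate_catalog(cfg)
        gtins = products.loc[products["item_number"].str.len() == 13, "item_number"]
        assert len(gtins) > 0
        assert all(is_valid_gtin13(g) for g in gtins)

    def test_topn_popularity_share_by_direct_summation(self):
        cfg = CohortConfig(n_products=5000, zipf_exponent=1.2, seed=3)
        products, _ = generate_catalog(cfg)
        w = np.sort(products["popularity_weight"].to_numpy())[::-1]
        # brute-force oracle: normalized Zipf weights summed over ranks
        ranks = np.arange(1, 5001, dtype=float)
        zipf = ranks**-1.2
        zipf /= zipf.sum()
        assert w.sum() == pytest.approx(1.0)
        assert w[:1000].sum() == pytest.approx(zipf[:1000].sum(), rel=1e-9)

    def test_every_product_has_one_true_category(self):
        products, _ = generate_catalog(CohortConfig(n_products=200, seed=4))
        assert products["category_id"].notna().all()
        assert len(products) == 200


class TestDatabases:
    def test_full_coverage_every_gtin_matchable(self):
        cfg = CohortConfig(n_products=150, specific_db_coverage=1.0, seed=5)
        products, truth = generate_catalog(cfg)
        _, dbs = generate_databases(products, truth, cfg)
        gtins = set(products.loc[products["item_number"].str.len() == 13, "item_number"])
        assert {r.gtin for r in dbs["gs1like"]} == gtins

    def test_zero_noise_specific_equals_generic(self):
        cfg = CohortConfig(
            n_products=150, specific_db_coverage=1.0, nutrient_noise_sigma=0.0,
            nutrient_missing_prob=0.0, seed=5,
        )
        products, truth = generate_catalog(cfg)
        generic, dbs = generate_databases(products, truth, cfg)
        gen = {r.category_id: r.nutrients for r in generic}
        cat_of = products.set_index("item_number")["category_id"]
        food = products.set_index("item_number")["is_food"]
        for rec in dbs["gs1like"]:
            if food[rec.gtin]:
                for nut, val in rec.nutrients.items():
                    assert val == pytest.approx(gen[cat_of[rec.gtin]][nut], abs=1e-3)

    def test_membership_reproducible(self):
        cfg = CohortConfig(n_products=200, specific_db_coverage=0.5, seed=6)
        products, truth = generate_catalog(cfg)
        _, d1 = generate_databases(products, truth, cfg)
        _, d2 = generate_databases(products, truth, cfg)
        assert [r.gtin for r in d1["gs1like"]] == [r.gtin for r in d2["gs1like"]]

    def test_risk_scores_only_in_chemlike(self):
        cfg = CohortConfig(n_products=300, seed=7)
        products, truth = generate_catalog(cfg)
        _, dbs = generate_databases(products, truth, cfg)
        assert all(r.risk_score in {"A", "B", "C"} for r in dbs["chemlike"])
        assert all(r.risk_score is None for r in dbs["gs1like"])

    def test_pattern_columns_compile(self):
        cfg = CohortConfig(n_products=300, seed=8)
        products, truth = generate_catalog(cfg)
        generic, _ = generate_databases(products, truth, cfg)
        assert len({r.category_id for r in generic}) == len(generic)


class TestReceipts:
    def test_all_inactive_gives_empty_table(self):
        cfg = CohortConfig(
            n_participants=5, n_products=100, months=3, inactive_month_prob=1.0, seed=9
        )
        products, truth = generate_catalog(cfg)
        purchases, _ = generate_receipts(products, truth, cfg)
        assert purchases.n_lines == 0 and purchases.n_receipts == 0

    def test_degenerate_loyalty_concentrates_on_one_retailer(self):
        cfg = CohortConfig(
            n_participants=10, n_retailers=8, n_products=150, months=3,
            loyalty_concentration=1e-8, assortment_coverage=1.0,
            restricted_groups=(), seed=10,
        )
        products, truth = generate_catalog(cfg)
        purchases, _ = generate_receipts(products, truth, cfg)
        per = purchases.df.groupby("participant_id")["retailer_id"].nunique()
        assert (per == 1).all()

    def test_truth_preferences_sum_to_one(self, small_cohort):
        sums = small_cohort.truth.preferences.groupby("participant_id")["proportion"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_group_frequencies_converge_to_truth(self):
        cfg = CohortConfig(
            n_participants=5, n_retailers=6, n_products=300, months=24,
            receipts_per_month_mean=12, lines_per_receipt_mean=12,
            inactive_month_prob=0.0, seed=12,
        )
        data = generate_cohort(cfg)
        df = data.purchases.df
        group_of = data.truth.products.set_index("item_number")["group"]
        emp = (
            df.assign(group=df["item_number"].map(group_of))
            .groupby(["participant_id", "group"])
            .size()
            .groupby(level=0)
            .transform(lambda s: s / s.sum())
        )
        truth = data.truth.preferences.set_index(["participant_id", "group"])["proportion"]
        merged = pd.concat([emp.rename("emp"), truth], axis=1).fillna(0.0)
        # ~3500 lines per participant -> binomial SE well under 1.5pp
        assert (merged["emp"] - merged["proportion"]).abs().max() < 0.04

    def test_popularity_concentration_monotone_in_zipf_exponent(self):
        shares = []
        for expo in (0.6, 1.2, 1.8):
            vals = []
            for seed in range(3):
                cfg = CohortConfig(
                    n_participants=8, n_retailers=5, n_products=400, months=3,
                    zipf_exponent=expo, seed=40 + seed,
                )
                data = generate_cohort(cfg)
                counts = data.purchases.df.groupby("item_number").size()
                top = counts.sort_values(ascending=False).iloc[:40].sum()
                vals.append(top / counts.sum())
            shares.append(np.mean(vals))
        assert shares[0] < shares[1] < shares[2]


class TestCohortOutput:
    def test_byte_identical_outputs_across_runs(self, tmp_path, small_config):
        d1 = generate_cohort(small_config, tmp_path / "a")
        d2 = generate_cohort(small_config, tmp_path / "b")
        for name in ["receipts.jsonl", "generic_db.csv", "specific_gs1like.csv",
                     "truth_products.csv", "truth_preferences.csv"]:
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_config_yaml_round_trip(self, tmp_path, small_config):
        path = tmp_path / "cfg.yaml"
        small_config.to_yaml(path)
        assert CohortConfig.from_yaml(path) == small_config

    def test_truth_files_have_expected_sizes(self, tmp_path, small_config, small_cohort):
        write_cohort(small_cohort, tmp_path)
        products = pd.read_csv(tmp_path / "truth_products.csv")
        prefs = pd.read_csv(tmp_path / "truth_preferences.csv")
        assert len(products) == small_config.n_products
        assert prefs["participant_id"].nunique() == small_config.n_participants
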