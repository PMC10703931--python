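"""Name preprocessing, generic scoring/classification, GTIN cascade, enrich."""

import re

import pytest

from cpdtools import (
    CohortConfig,
    EnrichmentConfig,
    GenericFoodRecord,
    ScoreWeights,
    SpecificProductRecord,
    classify_generic,
    enrich,
    evaluate_matching,
    export_review_queue,
    generate_cohort,
    match_specific,
    preprocess_name,
    score_generic_candidates,
)
from cpdtools.enrichment import (
    FLAG_AMBIGUOUS,
    FLAG_BELOW_THRESHOLD,
    FLAG_GREEDY,
    GenericMatcher,
    index_specific_dbs,
)


def cat(cid, **kw):
    base = dict(
        category_id=cid,
        category_name=cid,
        group="g",
        is_food=True,
        nutrients={"energy_kj": 100.0},
    )
    base.update(kw)
    return GenericFoodRecord(**base)


class TestPreprocessName:
    def test_pack_count_extracted(self):
        tokens, attrs = preprocess_name("apples 6-pack")
        assert tokens == ["apples"]
        assert attrs == {"pack_count": 6}

    def test_organic_and_volume_extracted(self):
        tokens, attrs = preprocess_name("ØKO skimmed milk 1l")
        assert tokens == ["skimmed", "milk"]
        assert attrs["organic"] is True
        assert attrs["volume_ml"] == 1000

    def test_weight_in_kg_converted_to_g(self):
        _, attrs = preprocess_name("potatoes 2kg")
        assert attrs["weight_g"] == 2000

    def test_empty_after_stripping(self):
        tokens, attrs = preprocess_name("500g")
        assert tokens == [] and attrs == {"weight_g": 500}

    def test_stopwords_and_abbreviations(self):
        tokens, _ = preprocess_name("skm milk tilbud", abbreviations={"skm": "skimmed"})
        assert tokens == ["skimmed", "milk"]

    def test_origin_marker(self):
        tokens, attrs = preprocess_name("danish butter 250g")
        assert attrs["origin"] == "DK" and tokens == ["butter"]


class TestScoring:
    db = [
        cat("milk_skimmed", pattern_type="milk", pattern_fat="skimmed"),
        cat("milk_whole", pattern_type="milk", pattern_fat="whole"),
    ]

    def test_default_weights_hand_example(self):
        ranked = score_generic_candidates(["skimmed", "milk"], self.db)
        assert [(c.category_id, c.score) for c in ranked] == [
            ("milk_skimmed", 5.0),
            ("milk_whole", 4.0),
        ]

    def test_no_hits_empty(self):
        assert score_generic_candidates(["banana"], self.db) == []

    def test_tie_breaks_lexicographically(self):
        ranked = score_generic_candidates(["milk"], self.db)
        assert [c.category_id for c in ranked] == ["milk_skimmed", "milk_whole"]
        assert ranked[0].score == ranked[1].score

    def test_word_boundary_prevents_substring_hits(self):
        db = [cat("bread_rye", pattern_type="bread")]
        assert score_generic_candidates(["crispbread"], db) == []

    def test_custom_weights(self):
        ranked = score_generic_candidates(
            ["skimmed", "milk"], self.db, ScoreWeights(w_type=10, w_fat=0.5)
        )
        assert ranked[0].score == 10.5


class TestClassify:
    def test_margin_one_accepted_margin_two_required_ambiguous(self):
        ranked = score_generic_candidates(["skimmed", "milk"], TestScoring.db)
        ok = classify_generic(ranked, min_score=4, min_margin=1)
        assert ok.matched and ok.category_id == "milk_skimmed" and not ok.flags
        amb = classify_generic(ranked, min_score=4, min_margin=2)
        assert not amb.matched and FLAG_AMBIGUOUS in amb.flags

    def test_below_threshold(self):
        ranked = score_generic_candidates(["skimmed"], TestScoring.db)  # score 1
        cls = classify_generic(ranked, min_score=4)
        assert not cls.matched and FLAG_BELOW_THRESHOLD in cls.flags

    def test_greedy_flag_on_generic_only_win(self):
        db = [cat("misc_food", pattern_generic="food")]
        ranked = score_generic_candidates(["food"], db, ScoreWeights(w_generic=4))
        cls = classify_generic(ranked, min_score=4, min_margin=1)
        assert cls.matched and FLAG_GREEDY in cls.flags

    def test_empty_ranking_unmatched(self):
        cls = classify_generic([])
        assert not cls.matched and FLAG_BELOW_THRESHOLD in cls.flags


def spec_record(gtin, source, **kw):
    return SpecificProductRecord(
        gtin=gtin, product_name="x", nutrients={}, source_db=source, **kw
    )


class TestMatchSpecific:
    gtin = "5701234567899"

    def test_single_hit(self):
        dbs = index_specific_dbs({"chemlike": [spec_record(self.gtin, "chemlike", risk_score="B")]})
        hit = match_specific(self.gtin, dbs)
        assert hit.source_db == "chemlike" and hit.risk_score == "B"

    def test_priority_and_merge(self):
        dbs = index_specific_dbs(
            {
                "gs1like": [spec_record(self.gtin, "gs1like")],
                "offlike": [
                    SpecificProductRecord(
                        gtin=self.gtin, product_name="x", nutrients={},
                        ingredients=("water", "sugar"), source_db="offlike",
                    )
                ],
            }
        )
        hit = match_specific(self.gtin, dbs)
        assert hit.source_db == "gs1like"
        assert hit.ingredients == ("water", "sugar")  # merged from the lower-priority hit

    def test_absent_everywhere(self):
        assert match_specific(self.gtin, index_specific_dbs({"gs1like": []})) is None


class TestEnrich:
    def test_full_coverage_clean_names_all_matched(self):
        cfg = CohortConfig(
            n_participants=10, n_retailers=5, n_products=120, months=3,
            specific_db_coverage=1.0, name_noise_level=0.0,
            internal_code_frac=0.0, excluded_code_frac=0.0,
            unmatchable_name_frac=0.0, seed=11,
        )
        data = generate_cohort(cfg)
        res = enrich(data.purchases, data.generic_db, data.specific_dbs)
        assert res.summary.frac_unique_matched == 1.0

    def test_zero_coverage_all_matches_generic(self):
        cfg = CohortConfig(
            n_participants=10, n_retailers=5, n_products=120, months=3,
            specific_db_coverage=0.0, name_noise_level=0.0,
            internal_code_frac=0.0, excluded_code_frac=0.0,
            unmatchable_name_frac=0.0, seed=11,
        )
        data = generate_cohort(cfg)
        res = enrich(data.purchases, data.generic_db, data.specific_dbs)
        sources = set(res.match_table["match_source"])
        assert sources == {"generic"}
        assert res.summary.frac_unique_matched == 1.0

    def test_totality_and_exclusive_partition(self, small_cohort, small_enriched):
        mt = small_enriched.match_table
        uniques = small_cohort.purchases.df[["item_number", "item_name"]].drop_duplicates()
        assert len(mt) == len(uniques)
        allowed = {"specific:gs1like", "specific:chemlike", "specific:offlike", "generic", "unmatched"}
        assert set(mt["match_source"]) <= allowed

    def test_excluded_item_numbers_flagged_without_gtin(self, small_enriched):
        mt = small_enriched.match_table
        digits = mt["item_number_raw"].str.replace(r"\D", "", regex=True).str.len()
        short_or_long = (digits < 3) | (digits > 14)
        assert short_or_long.any()
        assert mt.loc[short_or_long, "flag_excluded_item_number"].all()
        assert (mt.loc[short_or_long, "gtin"] == "").all()

    def test_summary_deterministic_across_runs(self, small_cohort):
        r1 = enrich(small_cohort.purchases, small_cohort.generic_db, small_cohort.specific_dbs)
        r2 = enrich(small_cohort.purchases, small_cohort.generic_db, small_cohort.specific_dbs)
        assert r1.summary == r2.summary
        assert r1.match_table.equals(r2.match_table)

    def test_review_queue_sorted_by_volume_and_covers_all_flagged(self, small_enriched):
        queue = export_review_queue(small_enriched.match_table)
        vols = queue["total_quantity"].to_numpy()
        assert (vols[:-1] >= vols[1:]).all()
        mt = small_enriched.match_table
        n_flagged = (
            mt["flag_greedy"] | mt["flag_ambiguous"] | mt["flag_below_threshold"]
            | (mt["match_source"] == "unmatched")
        ).sum()
        assert len(queue) == n_flagged


def brute_force_assignments(cohort, config: EnrichmentConfig):
    """Independent exhaustive matcher: plain re over every pattern column of
    every category, straight application of the scoring formula."""
    weights = {
        "pattern_type": config.weights.w_type,
        "pattern_specific": config.weights.w_specific,
        "pattern_generic": config.weights.w_generic,
        "pattern_brand": config.weights.w_brand,
        "pattern_flavor": config.weights.w_flavor,
        "pattern_fat": config.weights.w_fat,
    }
    out = {}
    uniques = cohort.purchases.df[["item_number", "item_name"]].drop_duplicates()
    for number, name in uniques.itertuples(index=False):
        tokens, _ = preprocess_name(name, config.stopwords, config.abbreviations)
        joined = " ".join(tokens)
        scored = []
        for rec in cohort.generic_db:
            s = 0.0
            for col, w in weights.items():
                pat = getattr(rec, col)
                if pat and re.search(rf"\b(?:{pat})\b", joined):
                    s += w
            if s > 0:
                scored.append((-s, rec.category_id))
        scored.sort()
        if not scored or -scored[0][0] < config.min_score:
            out[(number, name)] = None
            continue
        best_score = -scored[0][0]
        runner = -scored[1][0] if len(scored) > 1 else 0.0
        if best_score - runner < config.min_margin:
            out[(number, name)] = None
        else:
            out[(number, name)] = scored[0][1]
    return out


def test_enrich_agrees_with_brute_force_matcher_on_small_catalog():
    cfg = CohortConfig(
        n_participants=8, n_retailers=4, n_products=50, months=3,
        specific_db_coverage=0.0, seed=5,
    )
    data = generate_cohort(cfg)
    config = EnrichmentConfig()
    res = enrich(data.purchases, data.generic_db, data.specific_dbs, config)
    oracle = brute_force_assignments(data, config)
    for rec in res.match_table.itertuples(index=False):
        expected = oracle[(rec.item_number_raw, rec.item_name_raw)]
        got = rec.category_id or None
        assert got == expected, (rec.item_number_raw, rec.item_name_raw)


def test_accuracy_degrades_monotonically_with_name_noise():
    """Classification accuracy over all products (unmatched = wrong) falls
    as the name corruption probability rises, averaged over seeds."""
    levels = [0.0, 0.4, 0.8]
    mean_acc = []
    for noise in levels:
        accs = []
        for seed in range(3):
            cfg = CohortConfig(
                n_participants=6, n_retailers=4, n_products=200, months=2,
                specific_db_coverage=0.0, name_noise_level=noise,
                internal_code_frac=0.0, excluded_code_frac=0.0,
                unmatchable_name_frac=0.0, seed=100 + seed,
            )
            data = generate_cohort(cfg)
            res = enrich(data.purchases, data.generic_db, data.specific_dbs)
            ev = evaluate_matching(res.match_table, data.truth)
            if ev.n_evaluated:
                assert ev.exact_rate_unique == pytest.approx(1.0, abs=0.05) or noise > 0
            correct = ev.exact_rate_unique * ev.n_evaluated if ev.n_evaluated else 0
            accs.append(correct / (ev.n_evaluated + ev.n_excluded_unmatched))
        mean_acc.append(sum(accs) / len(accs))
    assert mean_acc[0] == 1.0
    assert mean_acc[0] > mean_acc[1] > mean_acc[2]
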