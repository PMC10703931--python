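# cpdtools

Tools for turning raw consumer purchase data (CPD) — receipt lines with an
item number, a terse item name, a price and a timestamp — into analyzable
exposure data, and for quantifying two of its main error sources: product
misclassification and incomplete retailer coverage.

The package is aimed at epidemiologists and nutrition researchers working
with digital-receipt or loyalty-card cohorts, where purchases from many
retail chains must be linked to food-composition and product databases
before diet, alcohol, tobacco or chemical exposures can be estimated.

## What it does

**Product enrichment.** Each unique product (an `(item_number, item_name)`
pair) passes through a cascade:

1. *Item-number filter*: numbers with fewer than 3 or more than 14 digits
   are excluded; 8/12/13/14-digit numbers are normalized to GTIN-13 and
   validated with the mod-10 check digit; other lengths are kept as
   supplier-internal codes eligible only for name matching.
2. *GTIN lookup* in one or more specific product databases (a GS1-like
   supplier database, a Kemiluppen-like chemical-risk database, an Open
   Food Facts-like crowd database), with source priority and annotation
   merging.
3. *Generic name matching*: the item name is cleaned (units, pack counts,
   organic/origin markers extracted; stopwords and abbreviations handled)
   and scored against every category of a generic food database whose
   regex columns describe brands, product types, specific and generic
   descriptors, flavors and fat content:

   `score(c) = Σ_k w_k · 1[pattern_k(c) matches name]`,
   with default weights w_type=4, w_specific=3, w_brand=2,
   w_generic=w_flavor=w_fat=1.

   The best category is accepted iff `score ≥ 4` and it beats the
   runner-up by ≥ 1; near-ties are flagged *ambiguous*, wins on broad
   descriptor evidence only are flagged *greedy*, and all flagged or
   unmatched products are exported to a manual-review queue sorted by
   purchase volume.

**Nutrient concordance.** For products matched both ways, generic
(category-average) and specific (brand-level) per-100 g values are
compared with the modified relative difference

`d(a, b) = |a − b| / max(a, b)  ∈ [0, 1]`,

which is symmetric, scale-invariant, 0 iff the values agree and 1 when one
source reports zero. Cumulative distributions and per-category medians are
produced with unique-product or purchase-volume weighting.

**Retailer coverage.** For each participant and retailer subset S, the
proportion p̂_g(S) of purchases in each of the top-K food groups is
compared with the all-retailer profile: percentage-point differences
`100·(p̂_g(S) − p̂_g(full))`, relative differences
`100·(p̂_g(S) − p̂_g(full))/p̂_g(full)` (exactly −100% when a group is
bought entirely outside S), and their dispersion across participants for
individual retailers and cumulative prefixes of the purchase-volume
ranking.

**Synthetic cohort.** Because real receipt cohorts are privacy-restricted,
a seeded generator produces a full study: a Zipf-skewed product catalog
with valid GTINs and tokenized names, the generic and specific databases
(with log-normal brand-vs-category nutrient noise as known ground truth),
Dirichlet per-participant group preferences and retailer loyalty,
overlapping retailer assortments with restricted groups (a tobacco-like
group carried by few retailers), noisy/abbreviated receipt names, and
inactive months. Every quantity the analyses estimate has a generator-side
truth, enabling parameter-recovery tests.

## Worked example

`examples/retailer_coverage.py` simulates an 80-participant, 20-retailer,
12-month cohort (seed 3), enriches it, and runs the coverage analysis:

```python
data = generate_cohort(CohortConfig(n_participants=80, n_retailers=20,
                                    n_products=600, months=12, seed=3))
result = enrich(data.purchases, data.generic_db, data.specific_dbs)
lines = result.line_table[result.line_table["group"] != ""]
groups = top_food_groups(lines, 20, {r.group: r.is_food for r in data.generic_db})
cov = coverage_differences(lines, groups)
```

`python examples/retailer_coverage.py` prints:

```
relative difference in group shares vs all retailers (median [p10; p90]):
  largest 1 retailer(s):    -7.7%  [-100.0%;  105.4%]
  largest 2 retailer(s):    -5.0%  [-100.0%;   90.1%]
  largest 4 retailer(s):    -1.6%  [-100.0%;   59.7%]

pooled SD of percentage-point differences by retailers combined:
   1 retailer(s): SD =  4.91 pp
   4 retailer(s): SD =  3.07 pp
  20 retailer(s): SD =  0.00 pp
```

Read: with data from a single retailer the median group share is
underestimated by ~8% and at least a tenth of the (participant, group)
cells miss *all* purchases of a group (−100%, e.g. an apparent non-smoker
buying cigarettes elsewhere); combining retailers shrinks the distortion,
and the dispersion falls to exactly zero once every retailer contributes. `examples/` contains one narrative script per capability
(simulation, enrichment, nutrient concordance, coverage, evaluation).

## Command line

```bash
cpdtools run-all --config run.yaml      # simulate → enrich → compare →
                                        # coverage → describe → evaluate
```

Stages can also be run individually (`simulate`, `enrich`,
`compare-nutrients`, `coverage`, `describe`, `evaluate`); all intermediate
results are flat CSV/JSON-lines files and a JSON manifest records the
config hash and per-stage counters, so reruns are byte-identical.

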