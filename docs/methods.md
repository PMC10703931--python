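# Methods

This note documents the models, conventions and numerical choices behind
`cpdtools`, and what the synthetic cohort does and does not establish
about real receipt data.

## Data model

A *receipt line* is the atomic observation: `(participant_id, retailer_id,
purchase_datetime, item_number, item_name, unit_price, quantity,
discount)`. A *receipt* is the set of lines sharing the `(participant,
retailer, datetime)` triple; grouping is a pure function of those keys, so
all aggregates are invariant to row order. Currency is held internally as
integer øre (1/100 DKK): spend summaries are exact sums of integers and
therefore order-independent, and the on-disk decimal-DKK representation
round-trips exactly at two decimals. Timestamps are ISO-8601,
timezone-naive local purchase time; only calendar-month granularity is
used downstream. JSON-lines is the canonical interchange format; CSV is
supported with the same documented header.

A *unique product* is the `(item_number, item_name)` pair, not the number
alone, because supplier-internal numbers can be reused across retailers.

## Item-number normalization

Non-digits are stripped. Fewer than 3 or more than 14 digits ⇒ excluded
(`excluded_item_number`); such products still undergo name matching, since
the exclusion concerns only number-based linkage. 8- and 12-digit numbers
are left-padded to 13 (zero padding preserves the mod-10 check digit,
which is positional from the right); a 14-digit number with a leading zero
is stripped to 13; 13 is used as-is. Candidates failing the check digit —
and all 3–7 and 9–11 digit numbers — are treated as supplier-internal
codes rather than rejected, because real receipts mix GTINs with shorter
supplier-generated barcodes. `normalize_item_number` is total: every
outcome is encoded in its result, never an exception.

## Generic name matching

Names are lower-cased and NFKC-normalized; unit expressions (weight,
volume, pack count), organic markers and origin markers are parsed into
extracted attributes and removed; stopwords are dropped and configured
abbreviations expanded; token order is preserved. Patterns are evaluated
on the space-joined token string wrapped in word boundaries
(`\b(?:pattern)\b`), which permits multi-word stems while preventing
substring false hits (`bread` does not fire inside `crispbread`).

The score of category *c* is the weighted sum of its six pattern-column
hits. The weights (type 4, specific 3, brand 2, generic/flavor/fat 1) and
thresholds (accept iff score ≥ 4 and runner-up margin ≥ 1) are explicit
configuration, chosen so that a type-stem hit alone reaches the threshold
and any variant evidence resolves same-type ties. Ties and insufficient
margins are *ambiguous* (not accepted); sufficient score won on a
broad-descriptor (`pattern_generic`) hit alone is *greedy* — accepted but
queued for review, since broad evidence is the classic source of silent
misclassification. Ranking is deterministic: descending score, then
lexicographic category id. On catalogs where exhaustive search is
feasible the pipeline provably agrees with a brute-force scorer applying
the same formula (tested).

Products matched by GTIN are additionally assigned a generic category via
their *database* product name (clean, not the noisy receipt name), so the
nutrient comparison always has both sources; specific sources take
priority gs1like > chemlike > offlike, with ingredients and risk scores
merged across all hits.

## Nutrient concordance

For non-negative per-100 g values the modified relative difference is
`|a − b| / max(a, b)`. Conventions: `d(0, 0) = 0` (identical values never
register a difference; the definition is otherwise silent on the zero
case), negative inputs are a domain error. Both sides are compared per
100 g with no serving-size reconciliation. Medians are computed over
unique products (each product once); purchase-volume weighting is offered
as a labelled alternative for the cumulative distributions. The CDF is a
right-continuous step function, monotone by construction, with a terminal
grid point at `rel_diff = 1`.

## Retailer coverage

"Proportion of purchases" is quantity-weighted line counts by default
(line-count-only available); the denominator for a subset is *all* the
participant's purchases within that subset, so top-K proportions sum to
≤ 1. Counts stay integer until the final division, which makes the
identity case exact: for the full-retailer subset every percentage-point
and relative difference is 0.0 with no floating-point leakage (the
relative difference divides before scaling by 100 so the −100% boundary is
also exact). Groups with `p_full = 0` have undefined relative difference
(0/0) but a defined percentage-point difference; participants with no
purchases inside a subset are flagged (`zero_subset_flag`), kept in the
output, and excluded from dispersion and percentile pooling. Cumulative
subsets are prefixes of the retailer ranking by total purchase-line count
(deterministic id tie-break) — the natural reading of "cumulatively
combined". Percentiles pool over participant × group cells and use linear
interpolation.

## Descriptive conventions

Months on study = whole calendar months between first and last receipt,
inclusive; receipts/month and spend/month use this denominator. An
inactive month is a whole calendar month strictly inside that span with
zero purchases (boundary months have receipts by construction). Quartiles
use linear interpolation. Purchase concentration ranks unique products by
line count (quantity weighting optional). Enrollment time runs from the
first receipt to a configurable analysis date, binned <1, 1–2, …, 5+
years.

## Evaluation

Exact match = assigned category equals the true category; group match =
agreement at the coarser food-group layer (the same layer the coverage
analysis uses — hence the two-level `category → group` hierarchy in the
generic DB schema). Unmatched products are excluded from the rate
denominators but reported (`n_excluded_unmatched`), so renaming unmatched
products can never move the rates. The optional fixed-size random sample
is seeded and uniform over unique products by default, with
volume-weighted sampling available.

## The synthetic cohort

The generator emulates the statistical structure of multi-retailer
digital-receipt data with known ground truth. Defaults (all configurable):
200 participants, 34 retailers, 24 months, 1 500 products, Zipf exponent
1.1, 20 food + 3 non-food groups, 8.4 shopping trips and ~10 lines per
receipt per month, 10% inactive months, specific-database coverage 0.6
(popularity-weighted), log-normal nutrient noise σ = 0.3, name-corruption
probability 0.1, assortment coverage 0.9 with the tobacco-like group
carried by 8 retailers. Trip frequency, product price level (~20 DKK
median), merchants used (~13–15) and inactive-month counts were chosen to
sit in the range typical of published receipt cohorts; the Zipf skew makes
a small product set dominate purchases.

Mechanisms worth knowing when interpreting tests:

* **Preferences and loyalty** are Dirichlet draws — one concentration knob
  per heterogeneity axis. Group sampling per line is unconditional on the
  retailer, so per-participant group frequencies converge to the truth
  vector (binomial rate); the *retailer* is the trip's loyalty draw unless
  it carries no product of the sampled group, in which case the line
  detours to a loyalty-weighted carrier. This keeps receipts coherent
  (one retailer per trip, with occasional same-day second receipts) while
  still concentrating restricted groups at their few carriers — the
  mechanism behind the apparent-non-smoker distortion.
* **Names** are built from (organic, brand, type stem, variant, pack)
  tokens; the regex columns of the generic DB are generated from the same
  vocabulary, so noise-free names classify with 100% accuracy and every
  accepted match has margin ≥ 1 by construction. Corruption (applied once
  per product, with the configured probability) is vowel-dropping,
  truncation to 20 characters, stray unit tokens, or case mangling; only
  the first two can break matching, so accuracy degrades roughly linearly
  in the noise level. A separate fraction of products carries opaque
  supplier shorthand (consonant abbreviations + digit codes) that no
  pattern can match — these are matchable only via GTIN, emulating the
  genuinely unmatchable tail of real receipt vocabularies.
* **Nutrients**: specific-database values are the category's generic
  values times `exp(σZ)`, `Z ~ N(0,1)`, per nutrient. The modified
  relative difference of such a pair is `1 − exp(−σ|Z|)`, so the expected
  median is known in closed form and by direct Monte-Carlo — the
  calibration target of the concordance stage.
* **Determinism**: one global seed; each stage (catalog, databases,
  receipts, names) and each participant derives an independent generator
  from fixed offsets, so outputs are byte-identical across runs and
  stable under downstream config changes.

What the generator does **not** model: real Danish price structure,
household composition, seasonal or promotional dynamics, within-category
brand heterogeneity of names, retailer-specific name formatting, and the
true distribution of lines per receipt or assortment overlap (not
publicly known; defaults chosen for testability). Passing tests therefore
establish the correctness and calibration of the *methods*, not the field
accuracy of any particular matching vocabulary on real receipts.

## Problem sizes

The test suite exercises the full default scale (200 × 34 × 24) where the
property under test concerns cohort structure, and 20-seed replicates for
seed-averaged claims (dispersion convergence, volume-vs-unique ordering);
smaller cohorts are used where the property is scale-free (statistic
identities, fixtures with hand-computed answers). The acceptance script
runs the complete workflow at the default scale in well under a minute.
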