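"""Score the enrichment output against the generator's ground truth.

Exact = correct generic category; group = correct coarser food group
(e.g. right milk, wrong fat level).  Unmatched products are excluded
from the denominators but counted separately.
"""

from cpdtools import CohortConfig, enrich, evaluate_matching, generate_cohort

data = generate_cohort(
    CohortConfig(n_participants=40, n_products=500, months=8, name_noise_level=0.2, seed=19)
)
result = enrich(data.purchases, data.generic_db, data.specific_dbs)

ev = evaluate_matching(result.match_table, data.truth, sample_n=300, seed=1)
print(f"evaluated {ev.n_evaluated} of a 300-product random sample "
      f"({ev.n_excluded_unmatched} unmatched products excluded)")
print(f"exact matches: {100 * ev.exact_rate_unique:.1f}% of unique products, "
      f"{100 * ev.exact_rate_volume:.1f}% by purchase volume")
print(f"group matches: {100 * ev.group_rate_unique:.1f}% of unique products, "
      f"{100 * ev.group_rate_volume:.1f}% by purchase volume")
print("\nconfusion between true and assigned groups (head):")
print(ev.confusion.head(6).to_string(index=False))
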