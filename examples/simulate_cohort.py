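"""Generate a small synthetic receipt cohort and summarize its behaviour.

The generator emulates multi-retailer digital-receipt data: Zipf-skewed
product popularity, Dirichlet per-participant food-group preferences and
retailer loyalty, overlapping retailer assortments, and inactive months.
"""

from cpdtools import CohortConfig, generate_cohort, purchase_concentration, summarize_cohort

config = CohortConfig(n_participants=50, n_retailers=12, n_products=600, months=12, seed=42)
data = generate_cohort(config)

print(f"{data.purchases.n_lines} purchase lines on {data.purchases.n_receipts} receipts")
print(f"{len(data.generic_db)} generic categories; "
      + ", ".join(f"{k}: {len(v)} products" for k, v in data.specific_dbs.items()))

summary = summarize_cohort(data.purchases)
for name in ("receipts_per_month", "spend_per_month_dkk", "n_merchants", "inactive_months"):
    m = summary.metrics[name]
    print(f"{name:22s} median {m.median:8.1f}  IQR [{m.q1:.1f}-{m.q3:.1f}]  range ({m.min:.1f}-{m.max:.1f})")

share = purchase_concentration(data.purchases, 100)
print(f"top-100 products account for {100 * share:.1f}% of all purchase lines "
      "(popularity is Zipf-skewed, so a small set of products dominates)")
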