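"""Scoring of enrichment output against synthetic ground truth.

Mirrors a manual matching assessment: a product is an *exact* match when
its assigned generic category equals the true category, and a *group*
match when only the coarser food-group layer agrees (e.g. a milk product
matched to the wrong milk subtype).  Unmatched products are excluded from
the rate denominators but counted.  Also validates the coverage
estimator: full-data group proportions should recover the generator's
per-participant preference vectors within binomial sampling error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import GroundTruth


@dataclass
class MatchingEvaluation:
    exact_rate_unique: float
    exact_rate_volume: float
    group_rate_unique: float
    group_rate_volume: float
    confusion: pd.DataFrame        # true_group x assigned_group counts
    n_evaluated: int
    n_excluded_unmatched: int

    def as_dict(self) -> dict:
        return {
            "exact_rate_unique": self.exact_rate_unique,
            "exact_rate_volume": self.exact_rate_volume,
            "group_rate_unique": self.group_rate_unique,
            "group_rate_volume": self.group_rate_volume,
            "n_evaluated": self.n_evaluated,
            "n_excluded_unmatched": self.n_excluded_unmatched,
        }


def evaluate_matching(
    match_table: pd.DataFrame,
    truth: GroundTruth,
    sample_n: int | None = None,
    seed: int = 0,
    volume_weighted_sampling: bool = False,
) -> MatchingEvaluation:
    """Exact and group-level match rates, unique and volume-weighted.

    ``sample_n`` draws a seeded random sample of unique products before
    scoring (uniform by default, purchase-volume-weighted on request),
    emulating a manual review of a fixed number of products.  Raises if
    the truth table does not cover an evaluated product.
    """
    truth_products = truth.products.set_index("item_number")
    df = match_table.copy()

    missing = ~df["item_number_raw"].isin(truth_products.index)
    if missing.any():
        raise ValueError(
            f"ground truth missing item number(s): "
            f"{sorted(df.loc[missing, 'item_number_raw'].unique())[:5]}"
        )

    if sample_n is not None and sample_n < len(df):
        rng = np.random.default_rng(seed)
        if volume_weighted_sampling:
            p = df["total_quantity"].to_numpy(dtype=float)
            p = p / p.sum()
            idx = rng.choice(len(df), size=sample_n, replace=False, p=p)
        else:
            idx = rng.choice(len(df), size=sample_n, replace=False)
        df = df.iloc[np.sort(idx)]

    df = df.assign(
        true_category=truth_products.loc[df["item_number_raw"], "category_id"].to_numpy(),
        true_group=truth_products.loc[df["item_number_raw"], "group"].to_numpy(),
    )

    # the denominators exclude products without any category assignment
    evaluated = df[df["category_id"] != ""]
    n_excluded = len(df) - len(evaluated)
    if evaluated.empty:
        empty = pd.DataFrame()
        return MatchingEvaluation(np.nan, np.nan, np.nan, np.nan, empty, 0, n_excluded)

    exact = (evaluated["category_id"] == evaluated["true_category"]).to_numpy()
    group = (evaluated["group"] == evaluated["true_group"]).to_numpy()
    volume = evaluated["total_quantity"].to_numpy(dtype=float)

    confusion = (
        evaluated.groupby(["true_group", "group"])
        .size()
        .rename("n")
        .reset_index()
        .rename(columns={"group": "assigned_group"})
    )
    return MatchingEvaluation(
        exact_rate_unique=float(exact.mean()),
        exact_rate_volume=float((exact * volume).sum() / volume.sum()),
        group_rate_unique=float(group.mean()),
        group_rate_volume=float((group * volume).sum() / volume.sum()),
        confusion=confusion,
        n_evaluated=len(evaluated),
        n_excluded_unmatched=n_excluded,
    )


def evaluate_proportion_recovery(
    lines: pd.DataFrame,
    truth: GroundTruth,
) -> pd.DataFrame:
    """Full-data group-proportion estimates vs the generator's truth.

    ``lines`` must carry participant_id and a group column (the true or
    assigned group per line).  Proportions are line-count based, matching
    the generator's per-line group sampling.  Returns one row per
    (participant, group) with the estimate, the truth, the absolute error
    and a two-binomial-standard-error tolerance band at the participant's
    line count.
    """
    counts = lines.groupby(["participant_id", "group"]).size().rename("n_lines").reset_index()
    totals = lines.groupby("participant_id").size().rename("n_total")
    truth_long = truth.preferences.rename(columns={"proportion": "true_proportion"})

    merged = truth_long.merge(counts, on=["participant_id", "group"], how="left")
    merged["n_lines"] = merged["n_lines"].fillna(0).astype(int)
    merged = merged.merge(totals, on="participant_id", how="left")
    merged = merged[merged["n_total"].notna()]
    merged["n_total"] = merged["n_total"].astype(int)
    merged["estimated_proportion"] = merged["n_lines"] / merged["n_total"]
    merged["abs_error"] = (merged["estimated_proportion"] - merged["true_proportion"]).abs()
    p = merged["true_proportion"]
    merged["binomial_se"] = np.sqrt(p * (1 - p) / merged["n_total"])
    return merged[
        [
            "participant_id",
            "group",
            "estimated_proportion",
            "true_proportion",
            "abs_error",
            "n_lines",
            "n_total",
            "binomial_se",
        ]
    ]
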