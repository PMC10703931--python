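"""Nutrient concordance between generic and specific product databases.

For every product matched both to a generic category (by name) and to a
GTIN-keyed specific record, the modified relative difference
``|a - b| / max(a, b)`` is computed per nutrient.  The statistic lies in
[0, 1]: 0 means the two sources agree exactly, 1 means one source reports
zero while the other does not.  It is symmetric and scale-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .types import NUTRIENT_COLUMNS, GenericFoodRecord, SpecificProductRecord


def modified_relative_difference(a, b):
    """``|a - b| / max(a, b)`` for non-negative values (vectorized).

    By convention the difference of two zeros is 0 (identical values never
    register a difference).  Negative inputs raise a ValueError.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("nutrient values must be non-negative")
    denom = np.maximum(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, np.abs(a - b) / np.where(denom > 0, denom, 1.0), 0.0)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class NutrientComparisonTable:
    """Per-(product, nutrient) comparison records plus the exclusion count."""

    df: pd.DataFrame          # item key, nutrient, value_generic, value_specific, rel_diff, ...
    n_excluded: int           # products lacking either source

    def for_nutrient(self, nutrient: str) -> pd.DataFrame:
        return self.df[self.df["nutrient"] == nutrient]


def compare_nutrients(
    match_table: pd.DataFrame,
    generic_db: Sequence[GenericFoodRecord],
    specific_dbs: dict[str, Sequence[SpecificProductRecord]],
    source: str = "gs1like",
    nutrients: Sequence[str] = tuple(NUTRIENT_COLUMNS),
) -> NutrientComparisonTable:
    """Compare nutrients for all doubly matched products.

    A product qualifies when it was matched to the given specific source by
    GTIN *and* carries a generic category assignment; one record is emitted
    per (product, nutrient) where both sources report the nutrient.
    Products missing either source are excluded and counted.
    """
    generic_values = {r.category_id: r.nutrients for r in generic_db}
    specific_values = {
        r.gtin: r.nutrients for r in specific_dbs.get(source, []) if r.gtin_valid
    }

    eligible = match_table[
        (match_table["match_source"] == f"specific:{source}")
        & (match_table["category_id"] != "")
        & match_table["gtin"].isin(specific_values)
    ]
    n_excluded = len(match_table) - len(eligible)

    rows = []
    for rec in eligible.itertuples(index=False):
        gen = generic_values.get(rec.category_id, {})
        spec = specific_values[rec.gtin]
        for nut in nutrients:
            g = gen.get(nut)
            s = spec.get(nut)
            if g is None or s is None or pd.isna(g) or pd.isna(s):
                continue
            rows.append(
                {
                    "item_number_raw": rec.item_number_raw,
                    "item_name_raw": rec.item_name_raw,
                    "gtin": rec.gtin,
                    "category_id": rec.category_id,
                    "nutrient": nut,
                    "value_generic": float(g),
                    "value_specific": float(s),
                    "rel_diff": modified_relative_difference(float(g), float(s)),
                    "purchase_volume": rec.total_quantity,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "item_number_raw", "item_name_raw", "gtin", "category_id", "nutrient",
            "value_generic", "value_specific", "rel_diff", "purchase_volume",
        ],
    )
    return NutrientComparisonTable(df=df, n_excluded=n_excluded)


def cumulative_distribution(
    comparisons: NutrientComparisonTable | pd.DataFrame,
    nutrient: str,
    weighting: str = "unique",
) -> pd.DataFrame:
    """Empirical CDF of the relative difference for one nutrient.

    ``unique`` weighting counts each product once; ``volume`` weights by
    purchase volume.  The returned step function is monotone non-decreasing
    and reaches 1.0 at rel_diff = 1.  Empty input raises ValueError.
    """
    df = comparisons.df if isinstance(comparisons, NutrientComparisonTable) else comparisons
    sub = df[df["nutrient"] == nutrient]
    if sub.empty:
        raise ValueError(f"no comparisons available for nutrient {nutrient!r}")
    if weighting == "unique":
        weights = np.ones(len(sub))
    elif weighting == "volume":
        weights = sub["purchase_volume"].to_numpy(dtype=float)
    else:
        raise ValueError("weighting must be 'unique' or 'volume'")
    order = np.argsort(sub["rel_diff"].to_numpy(), kind="stable")
    values = sub["rel_diff"].to_numpy()[order]
    cum = np.cumsum(weights[order]) / weights.sum()
    out = pd.DataFrame({"rel_diff": values, "cumulative_fraction": cum})
    out = out.groupby("rel_diff", as_index=False)["cumulative_fraction"].max()
    if out["rel_diff"].iloc[-1] < 1.0:
        out = pd.concat(
            [out, pd.DataFrame({"rel_diff": [1.0], "cumulative_fraction": [1.0]})],
            ignore_index=True,
        )
    return out


def group_medians(
    comparisons: NutrientComparisonTable | pd.DataFrame,
    nutrient: str = "energy_kj",
) -> pd.DataFrame:
    """Median relative difference per generic category, plus the overall
    median (category id ``__overall__``), each with its product count."""
    df = comparisons.df if isinstance(comparisons, NutrientComparisonTable) else comparisons
    sub = df[df["nutrient"] == nutrient]
    per_cat = (
        sub.groupby("category_id")["rel_diff"]
        .agg(median_rel_diff="median", n="size")
        .reset_index()
        .sort_values("category_id")
    )
    overall = pd.DataFrame(
        {
            "category_id": ["__overall__"],
            "median_rel_diff": [sub["rel_diff"].median() if len(sub) else np.nan],
            "n": [len(sub)],
        }
    )
    return pd.concat([per_cat, overall], ignore_index=True)
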