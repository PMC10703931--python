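"""Cohort descriptive statistics with explicit counting conventions.

Conventions (documented because receipt data has no natural denominator):
months on study are whole calendar months between the first and last
receipt inclusive; an inactive month is a whole calendar month strictly
inside that span with zero purchases; quartiles use linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import PurchaseTable

ENROLLMENT_BINS = ["<1y", "1-2y", "2-3y", "3-4y", "4-5y", "5+y"]


@dataclass
class MetricSummary:
    metric: str
    median: float
    q1: float
    q3: float
    min: float
    max: float

    def as_dict(self) -> dict:
        return {
            "metric": self.metric,
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
            "min": self.min,
            "max": self.max,
        }


@dataclass
class CohortSummary:
    """Median [IQR] (min-max) per purchase-behaviour metric, plus the
    inactive-month distribution and enrollment-time bin counts."""

    n_participants: int
    metrics: dict[str, MetricSummary]
    enrollment_bins: dict[str, int]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([m.as_dict() for m in self.metrics.values()])

    def as_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "metrics": {k: v.as_dict() for k, v in self.metrics.items()},
            "enrollment_bins": dict(self.enrollment_bins),
        }


def _summary(name: str, values: pd.Series) -> MetricSummary:
    v = values.to_numpy(dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    return MetricSummary(name, float(med), float(q1), float(q3), float(v.min()), float(v.max()))


def months_span(first: pd.Timestamp, last: pd.Timestamp) -> int:
    """Whole calendar months between two dates, inclusive of both ends."""
    return (last.year - first.year) * 12 + (last.month - first.month) + 1


def summarize_cohort(
    purchases: PurchaseTable,
    analysis_date: pd.Timestamp | None = None,
) -> CohortSummary:
    """Per-participant purchase-behaviour summary.

    Metrics: products per participant (quantity-weighted), average product
    price (DKK), receipts, receipts per month, spend per month (DKK, net of
    discounts), merchants used, and inactive months.  Enrollment time runs
    from the first receipt to ``analysis_date`` (default: the last receipt
    in the table).
    """
    df = purchases.df
    if df.empty:
        return CohortSummary(0, {}, {b: 0 for b in ENROLLMENT_BINS})
    if analysis_date is None:
        analysis_date = df["purchase_datetime"].max()

    per = []
    for pid, sub in df.groupby("participant_id"):
        receipts = sub[["retailer_id", "purchase_datetime"]].drop_duplicates()
        first, last = sub["purchase_datetime"].min(), sub["purchase_datetime"].max()
        months = months_span(first, last)
        spend_ore = int((sub["unit_price_ore"] * sub["quantity"] - sub["discount_ore"]).sum())
        years_enrolled = (analysis_date - first).days / 365.25
        per.append(
            {
                "participant_id": pid,
                "n_products": int(sub["quantity"].sum()),
                "avg_price_dkk": float(sub["unit_price_ore"].mean() / 100.0),
                "n_receipts": len(receipts),
                "receipts_per_month": len(receipts) / months,
                "spend_per_month_dkk": spend_ore / 100.0 / months,
                "n_merchants": sub["retailer_id"].nunique(),
                "inactive_months": _inactive_months_of(sub),
                "years_enrolled": years_enrolled,
            }
        )
    pdf = pd.DataFrame(per)

    metrics = {
        name: _summary(name, pdf[name])
        for name in [
            "n_products",
            "avg_price_dkk",
            "n_receipts",
            "receipts_per_month",
            "spend_per_month_dkk",
            "n_merchants",
            "inactive_months",
        ]
    }
    bins = {b: 0 for b in ENROLLMENT_BINS}
    for y in pdf["years_enrolled"]:
        idx = min(int(y), 5) if y >= 0 else 0
        bins[ENROLLMENT_BINS[idx]] += 1
    return CohortSummary(len(pdf), metrics, bins)


def _inactive_months_of(sub: pd.DataFrame) -> int:
    months = pd.PeriodIndex(sub["purchase_datetime"], freq="M")
    present = set(months)
    first, last = months.min(), months.max()
    span = pd.period_range(first, last, freq="M")
    # boundary months have receipts by construction and are never counted
    return int(sum(1 for m in span if m not in present))


def inactive_months(purchases: PurchaseTable, participant: str) -> int:
    """Whole calendar months with zero purchases strictly inside the
    participant's [first receipt month, last receipt month] span."""
    sub = purchases.df[purchases.df["participant_id"] == participant]
    if sub.empty:
        raise ValueError(f"unknown participant {participant!r}")
    return _inactive_months_of(sub)


def purchase_concentration(
    purchases: PurchaseTable,
    top_n: int,
    quantity_weighted: bool = False,
) -> float:
    """Fraction of all purchases accounted for by the top_n most frequently
    purchased unique products (identified by the (item_number, item_name)
    pair; ranked and weighted by line count, or by quantity if requested)."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    df = purchases.df
    if df.empty:
        raise ValueError("purchase table is empty")
    if quantity_weighted:
        counts = df.groupby(["item_number", "item_name"])["quantity"].sum()
    else:
        counts = df.groupby(["item_number", "item_name"]).size()
    counts = counts.sort_values(ascending=False, kind="stable")
    return float(counts.iloc[:top_n].sum() / counts.sum())
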