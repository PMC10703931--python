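"""Retailer-coverage analysis of purchase profiles.

How well does a subset of retailers recover a participant's full purchase
profile?  For each participant and retailer subset, the proportion of the
participant's purchase lines falling in each of the top-K food product
groups is compared with the all-retailer profile: the percentage-point
difference (subset minus full, on the 0-100 scale) and the relative
difference 100*(subset - full)/full.  A group bought only at retailers
outside the subset shows a relative difference of exactly -100% — the
mechanism by which e.g. a smoker evaluated on one retailer's data can look
like a non-smoker.  Dispersion of the differences across participants
quantifies how profile estimates stabilize as retailers are combined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

COVERAGE_COLUMNS = [
    "participant_id",
    "subset_type",
    "subset_label",
    "subset_size",
    "group",
    "p_subset",
    "p_full",
    "pp_difference",
    "rel_difference_pct",
    "zero_subset_flag",
]


def _line_weights(df: pd.DataFrame, weight: str) -> np.ndarray:
    if weight == "quantity" and "quantity" in df.columns:
        return df["quantity"].to_numpy(dtype=np.int64)
    return np.ones(len(df), dtype=np.int64)


def rank_retailers(df: pd.DataFrame) -> list[str]:
    """Retailers in descending order of total purchase-line count,
    deterministic tie-break by retailer id."""
    counts = df.groupby("retailer_id").size()
    return list(counts.sort_index().sort_values(ascending=False, kind="stable").index)


def top_food_groups(
    df: pd.DataFrame,
    k: int = 20,
    is_food: Mapping[str, bool] | None = None,
) -> list[str]:
    """The K most frequent food product groups by cohort-wide line count.

    ``is_food`` maps group label to food status; groups missing from the
    map (or all groups, when no map is given) count as food.  If fewer
    than K food groups exist, all are returned with a warning.
    """
    sub = df[df["group"].notna() & (df["group"] != "")]
    if is_food is not None:
        sub = sub[sub["group"].map(lambda g: bool(is_food.get(g, True)))]
    counts = sub.groupby("group").size()
    ranked = list(counts.sort_index().sort_values(ascending=False, kind="stable").index)
    if len(ranked) < k:
        warnings.warn(
            f"only {len(ranked)} food groups present, fewer than the requested {k}",
            stacklevel=2,
        )
    return ranked[:k]


@dataclass
class _Cube:
    """Integer purchase counts: participants x retailers x groups, plus
    all-group totals per participant x retailer (the denominator)."""

    participants: list[str]
    retailers: list[str]
    groups: list[str]
    counts: np.ndarray   # (P, R, G) int64
    totals: np.ndarray   # (P, R) int64, over ALL groups incl. non-top

    def subset_proportions(self, retailer_idx: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
        """(P, G) proportions within the subset and (P,) zero-subset mask.

        Counts stay integer until the final division, so a subset equal to
        the full set reproduces the full-data proportions bit-exactly.
        """
        idx = list(retailer_idx)
        num = self.counts[:, idx, :].sum(axis=1)
        den = self.totals[:, idx].sum(axis=1)
        zero = den == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            props = num / np.where(zero, 1, den)[:, None]
        props[zero] = np.nan
        return props, zero


def _build_cube(
    df: pd.DataFrame,
    groups: Sequence[str],
    weight: str = "quantity",
    participants: Sequence[str] | None = None,
    retailers: Sequence[str] | None = None,
) -> _Cube:
    df = df[df["group"].notna() & (df["group"] != "")]
    participants = sorted(df["participant_id"].unique()) if participants is None else list(participants)
    retailers = sorted(df["retailer_id"].unique()) if retailers is None else list(retailers)
    p_idx = {p: i for i, p in enumerate(participants)}
    r_idx = {r: i for i, r in enumerate(retailers)}
    g_idx = {g: i for i, g in enumerate(groups)}

    unknown = set(df["retailer_id"]) - set(retailers)
    if unknown:
        raise ValueError(f"unknown retailer id(s): {sorted(unknown)}")

    w = _line_weights(df, weight)
    pi = df["participant_id"].map(p_idx).to_numpy()
    ri = df["retailer_id"].map(r_idx).to_numpy()

    totals = np.zeros((len(participants), len(retailers)), dtype=np.int64)
    np.add.at(totals, (pi, ri), w)

    counts = np.zeros((len(participants), len(retailers), len(groups)), dtype=np.int64)
    in_top = df["group"].isin(g_idx).to_numpy()
    gi = df.loc[in_top, "group"].map(g_idx).to_numpy()
    np.add.at(counts, (pi[in_top], ri[in_top], gi), w[in_top])
    return _Cube(participants, retailers, list(groups), counts, totals)


def group_proportions(
    df: pd.DataFrame,
    participant: str,
    retailer_subset: Sequence[str],
    groups: Sequence[str],
    weight: str = "quantity",
) -> tuple[np.ndarray, bool]:
    """Proportion of one participant's purchases (restricted to the subset's
    retailers) falling in each group; denominator is all the participant's
    purchases within the subset.  Returns (vector, zero_subset_flag); the
    vector is NaN when the participant has no purchases in the subset."""
    if not retailer_subset:
        raise ValueError("retailer_subset must be non-empty")
    all_retailers = sorted(set(df["retailer_id"]) | set(retailer_subset))
    unknown = set(retailer_subset) - set(df["retailer_id"])
    if unknown:
        raise ValueError(f"unknown retailer id(s): {sorted(unknown)}")
    cube = _build_cube(df, groups, weight, retailers=all_retailers)
    if participant not in cube.participants:
        raise ValueError(f"unknown participant {participant!r}")
    pi = cube.participants.index(participant)
    idx = [cube.retailers.index(r) for r in retailer_subset]
    props, zero = cube.subset_proportions(idx)
    return props[pi], bool(zero[pi])


def default_subsets(ranking: Sequence[str], n_individual: int = 10) -> list[tuple[str, str, list[str]]]:
    """(subset_type, label, retailers) for the top-N individual retailers
    and every cumulative prefix of the ranking."""
    subsets: list[tuple[str, str, list[str]]] = []
    for r in ranking[:n_individual]:
        subsets.append(("individual", r, [r]))
    for k in range(1, len(ranking) + 1):
        subsets.append(("cumulative", f"top{k}", list(ranking[:k])))
    return subsets


def coverage_differences(
    df: pd.DataFrame,
    groups: Sequence[str],
    subsets: Sequence[tuple[str, str, Sequence[str]]] | None = None,
    weight: str = "quantity",
) -> pd.DataFrame:
    """Per participant x subset x group differences vs the full profile.

    ``subsets`` defaults to the top-10 individual retailers plus all
    cumulative prefixes of the purchase-volume ranking.  Zero-subset
    participants (no purchases within the subset) are flagged and carried
    in the output with undefined proportions; groups the participant never
    buys at all (p_full = 0) get an undefined relative difference but a
    defined percentage-point difference.
    """
    ranking = rank_retailers(df)
    if subsets is None:
        subsets = default_subsets(ranking)
    cube = _build_cube(df, groups, weight, retailers=ranking)
    r_index = {r: i for i, r in enumerate(cube.retailers)}

    full_props, _ = cube.subset_proportions(list(range(len(cube.retailers))))

    frames = []
    for subset_type, label, retailers in subsets:
        idx = [r_index[r] for r in retailers]
        props, zero = cube.subset_proportions(idx)
        pp = 100.0 * (props - full_props)
        # divide before scaling so a subset proportion of exactly zero
        # yields exactly -100 (the boundary of the statistic)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = 100.0 * ((props - full_props) / full_props)
        rel[full_props == 0] = np.nan
        n_p, n_g = pp.shape
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": np.repeat(cube.participants, n_g),
                    "subset_type": subset_type,
                    "subset_label": label,
                    "subset_size": len(retailers),
                    "group": np.tile(cube.groups, n_p),
                    "p_subset": props.ravel(),
                    "p_full": full_props.ravel(),
                    "pp_difference": pp.ravel(),
                    "rel_difference_pct": rel.ravel(),
                    "zero_subset_flag": np.repeat(zero, n_g),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[COVERAGE_COLUMNS]


def dispersion_summary(coverage: pd.DataFrame) -> pd.DataFrame:
    """SD across participants of the percentage-point differences.

    One row per (subset, group) plus a pooled row per subset (group
    ``__pooled__``, SD over participant x group cells).  Zero-subset
    participants are excluded; an SD over fewer than two values is
    reported as missing.
    """
    ok = coverage[~coverage["zero_subset_flag"] & coverage["pp_difference"].notna()]

    def _sd(s: pd.Series) -> float:
        return float(s.std(ddof=1)) if len(s) > 1 else np.nan

    per_group = (
        ok.groupby(["subset_type", "subset_label", "subset_size", "group"])["pp_difference"]
        .agg(sd_pp=_sd, n="size")
        .reset_index()
    )
    pooled = (
        ok.groupby(["subset_type", "subset_label", "subset_size"])["pp_difference"]
        .agg(sd_pp=_sd, n="size")
        .reset_index()
    )
    pooled["group"] = "__pooled__"
    out = pd.concat([per_group, pooled], ignore_index=True)
    return out.sort_values(
        ["subset_type", "subset_size", "subset_label", "group"], kind="stable"
    ).reset_index(drop=True)


def percentile_summary(
    coverage: pd.DataFrame,
    percentiles: Sequence[float] = (10, 50, 90),
    subset_sizes: Sequence[int] = (1, 2, 4),
) -> pd.DataFrame:
    """Percentiles of the relative difference for cumulative subsets.

    Values are pooled over participant x group cells (zero-subset
    participants and undefined cells excluded); percentiles use linear
    interpolation.
    """
    rows = []
    cumulative = coverage[coverage["subset_type"] == "cumulative"]
    for size in subset_sizes:
        sub = cumulative[
            (cumulative["subset_size"] == size)
            & ~cumulative["zero_subset_flag"]
            & cumulative["rel_difference_pct"].notna()
        ]
        values = sub["rel_difference_pct"].to_numpy()
        for pct in percentiles:
            rows.append(
                {
                    "subset_size": size,
                    "percentile": pct,
                    "rel_difference_pct": (
                        float(np.percentile(values, pct)) if len(values) else np.nan
                    ),
                    "n": len(values),
                }
            )
    return pd.DataFrame(rows, columns=["subset_size", "percentile", "rel_difference_pct", "n"])
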