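"""Product enrichment: item-number filtering, GTIN cascade, name matching.

The pipeline mirrors the enrichment flowchart of a multi-retailer receipt
stream: unique products (identified by the (item_number, item_name) pair,
since supplier-internal numbers can be reused across retailers) are first
filtered on item-number length, then looked up by GTIN in the specific
product databases, and the remainder matched to the generic food database
with a weighted regex score over preprocessed name tokens.  Products that
win on broad descriptor evidence only ("greedy"), tie with a runner-up
("ambiguous") or miss the score threshold are flagged for manual review.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict

from .gtin import ItemNumberStatus, normalize_item_number
from .types import GenericFoodRecord, PurchaseTable, SpecificProductRecord

# flag names -----------------------------------------------------------------
FLAG_EXCLUDED = "excluded_item_number"
FLAG_GREEDY = "greedy"
FLAG_AMBIGUOUS = "ambiguous"
FLAG_BELOW_THRESHOLD = "below_threshold"

#: specific databases in lookup priority order
SOURCE_PRIORITY = ("gs1like", "chemlike", "offlike")

MATCH_TABLE_COLUMNS = [
    "item_number_raw",
    "item_name_raw",
    "match_source",
    "gtin",
    "category_id",
    "group",
    "score",
    "runner_up_margin",
    "flag_excluded_item_number",
    "flag_greedy",
    "flag_ambiguous",
    "flag_below_threshold",
    "candidates",
    "weight_g",
    "volume_ml",
    "pack_count",
    "organic",
    "origin",
    "risk_score",
    "ingredients",
    "n_lines",
    "total_quantity",
]


class ScoreWeights(BaseModel):
    """Weights of the six regex evidence columns in the matching score."""

    model_config = ConfigDict(frozen=True)

    w_type: float = 4.0
    w_specific: float = 3.0
    w_generic: float = 1.0
    w_brand: float = 2.0
    w_flavor: float = 1.0
    w_fat: float = 1.0


#: maps pattern column -> (weight attribute, component key)
_PATTERN_WEIGHTS = {
    "pattern_type": ("w_type", "type"),
    "pattern_specific": ("w_specific", "specific"),
    "pattern_generic": ("w_generic", "generic"),
    "pattern_brand": ("w_brand", "brand"),
    "pattern_flavor": ("w_flavor", "flavor"),
    "pattern_fat": ("w_fat", "fat"),
}

DEFAULT_STOPWORDS = (
    "tilbud",
    "offer",
    "new",
    "ny",
    "pcs",
    "approx",
    "ca",
)

DEFAULT_ABBREVIATIONS = {
    "skm": "skimmed",
    "chok": "chocolate",
    "yogh": "yoghurt",
}


class EnrichmentConfig(BaseModel):
    """Tunable knobs of the enrichment stage (all defaults documented)."""

    model_config = ConfigDict(frozen=True)

    weights: ScoreWeights = ScoreWeights()
    min_score: float = 4.0
    min_margin: float = 1.0
    stopwords: tuple[str, ...] = DEFAULT_STOPWORDS
    abbreviations: dict[str, str] = dict(DEFAULT_ABBREVIATIONS)
    #: weight purchase volume by quantity (else line count)
    quantity_weighted_volume: bool = True


# ---------------------------------------------------------------------------
# name preprocessing and attribute extraction
# ---------------------------------------------------------------------------

_WEIGHT_RE = re.compile(r"(\d+(?:[.,]\d+)?)\s*(kg|g|gr)\b")
_VOLUME_RE = re.compile(r"(\d+(?:[.,]\d+)?)\s*(l|ltr|liter|cl|ml)\b")
_PACK_RE = re.compile(r"(\d+)\s*[- ]?\s*(pack|pak|pk|stk|x)\b")
_ORGANIC_TOKENS = {"øko", "oko", "eco", "org", "organic", "økologisk", "okologisk"}
_ORIGIN_TOKENS = {
    "dansk": "DK",
    "danish": "DK",
    "spansk": "ES",
    "spanish": "ES",
    "italiensk": "IT",
    "italian": "IT",
    "fransk": "FR",
    "french": "FR",
}
_TOKEN_RE = re.compile(r"[^\W\d_]+", re.UNICODE)


def preprocess_name(
    item_name_raw: str,
    stopwords: Sequence[str] = DEFAULT_STOPWORDS,
    abbreviations: dict[str, str] | None = None,
) -> tuple[list[str], dict]:
    """Clean a raw receipt item name for regex matching.

    Lower-cases, parses and strips unit/pack expressions into extracted
    attributes (weight_g, volume_ml, pack_count), pulls out organic and
    origin markers, drops stopwords and expands configured abbreviations.
    Token order is preserved.  An empty token list is allowed (it forces
    the product to be unmatched).
    """
    if abbreviations is None:
        abbreviations = DEFAULT_ABBREVIATIONS
    text = unicodedata.normalize("NFKC", str(item_name_raw)).lower()
    attributes: dict = {}

    m = _WEIGHT_RE.search(text)
    if m:
        value = float(m.group(1).replace(",", "."))
        attributes["weight_g"] = value * 1000 if m.group(2) == "kg" else value
        text = text[: m.start()] + " " + text[m.end() :]
    m = _VOLUME_RE.search(text)
    if m:
        value = float(m.group(1).replace(",", "."))
        unit = m.group(2)
        factor = 1000.0 if unit in {"l", "ltr", "liter"} else 10.0 if unit == "cl" else 1.0
        attributes["volume_ml"] = value * factor
        text = text[: m.start()] + " " + text[m.end() :]
    m = _PACK_RE.search(text)
    if m:
        attributes["pack_count"] = int(m.group(1))
        text = text[: m.start()] + " " + text[m.end() :]

    stopset = set(stopwords)
    tokens: list[str] = []
    for token in _TOKEN_RE.findall(text):
        if token in _ORGANIC_TOKENS:
            attributes["organic"] = True
            continue
        if token in _ORIGIN_TOKENS:
            attributes["origin"] = _ORIGIN_TOKENS[token]
            continue
        if token in stopset:
            continue
        token = abbreviations.get(token, token)
        tokens.extend(token.split())
    return tokens, attributes


# ---------------------------------------------------------------------------
# generic-database scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CandidateScore:
    """Score of one generic category for one product name."""

    category_id: str
    score: float
    components: dict = field(default_factory=dict, compare=False)


class GenericMatcher:
    """Precompiled scorer of clean-token strings against the generic DB.

    Patterns are evaluated on the space-joined clean-token string with
    word-boundary anchoring, so partial-word matching cannot fire inside an
    unrelated token.  Ranking is deterministic: descending score, then
    lexicographic category_id.
    """

    def __init__(self, generic_db: Sequence[GenericFoodRecord], weights: ScoreWeights | None = None):
        self.weights = weights or ScoreWeights()
        self.records = list(generic_db)
        self.by_id = {r.category_id: r for r in self.records}
        self._compiled: list[tuple[str, list[tuple[str, float, re.Pattern]]]] = []
        for rec in self.records:
            pats = []
            for column, (weight_attr, key) in _PATTERN_WEIGHTS.items():
                pattern = getattr(rec, column)
                if pattern:
                    compiled = re.compile(rf"\b(?:{pattern})\b")
                    pats.append((key, getattr(self.weights, weight_attr), compiled))
            self._compiled.append((rec.category_id, pats))

    def score(self, tokens: Sequence[str]) -> list[CandidateScore]:
        """All categories with a nonzero score, ranked."""
        joined = " ".join(tokens)
        results: list[CandidateScore] = []
        if not joined:
            return results
        for category_id, pats in self._compiled:
            total = 0.0
            components: dict = {}
            for key, weight, compiled in pats:
                if compiled.search(joined):
                    total += weight
                    components[key] = weight
            if total > 0:
                results.append(CandidateScore(category_id, total, components))
        results.sort(key=lambda c: (-c.score, c.category_id))
        return results


def score_generic_candidates(
    tokens: Sequence[str],
    generic_db: Sequence[GenericFoodRecord],
    weights: ScoreWeights | None = None,
) -> list[CandidateScore]:
    """Convenience one-shot scorer (builds a matcher; use GenericMatcher in loops)."""
    return GenericMatcher(generic_db, weights).score(tokens)


@dataclass(frozen=True)
class GenericClassification:
    """Accept/reject decision over a ranked candidate list."""

    category_id: Optional[str]
    score: float
    runner_up_margin: float
    flags: frozenset[str]

    @property
    def matched(self) -> bool:
        return self.category_id is not None


def classify_generic(
    ranked: Sequence[CandidateScore],
    min_score: float = 4.0,
    min_margin: float = 1.0,
) -> GenericClassification:
    """Apply score and runner-up-margin thresholds to a ranked candidate list.

    The best candidate is accepted iff score >= min_score and the margin to
    the runner-up is >= min_margin.  A sufficient score with an insufficient
    margin is flagged ``ambiguous`` (not accepted); an insufficient score is
    flagged ``below_threshold``.  An accepted winner whose evidence is a
    broad-descriptor (pattern_generic) hit only is flagged ``greedy`` but
    retained, feeding the manual-review queue.
    """
    if not ranked:
        return GenericClassification(None, 0.0, 0.0, frozenset({FLAG_BELOW_THRESHOLD}))
    best = ranked[0]
    margin = best.score - (ranked[1].score if len(ranked) > 1 else 0.0)
    if best.score < min_score:
        return GenericClassification(None, best.score, margin, frozenset({FLAG_BELOW_THRESHOLD}))
    if margin < min_margin:
        return GenericClassification(None, best.score, margin, frozenset({FLAG_AMBIGUOUS}))
    flags = set()
    if set(best.components) == {"generic"}:
        flags.add(FLAG_GREEDY)
    return GenericClassification(best.category_id, best.score, margin, frozenset(flags))


# ---------------------------------------------------------------------------
# specific-database cascade
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpecificMatch:
    """A GTIN hit, with annotations merged across all databases that hit."""

    source_db: str
    record: SpecificProductRecord
    ingredients: tuple[str, ...]
    risk_score: Optional[str]


def index_specific_dbs(
    specific_dbs: dict[str, Sequence[SpecificProductRecord]],
) -> dict[str, dict[str, SpecificProductRecord]]:
    """GTIN -> record lookup per source, skipping invalid-GTIN records."""
    return {
        source: {r.gtin: r for r in records if r.gtin_valid}
        for source, records in specific_dbs.items()
    }


def match_specific(
    gtin: str,
    indexed_dbs: dict[str, dict[str, SpecificProductRecord]],
) -> Optional[SpecificMatch]:
    """Exact-key lookup with source priority gs1like > chemlike > offlike.

    When several databases hit, the highest-priority source wins but
    ingredients and risk score from every hit are merged as secondary
    annotations.
    """
    hits = [
        (source, indexed_dbs[source][gtin])
        for source in SOURCE_PRIORITY
        if source in indexed_dbs and gtin in indexed_dbs[source]
    ]
    if not hits:
        return None
    primary_source, primary = hits[0]
    ingredients: tuple[str, ...] = ()
    risk: Optional[str] = None
    for _, rec in hits:
        if not ingredients and rec.ingredients:
            ingredients = rec.ingredients
        if risk is None and rec.risk_score is not None:
            risk = rec.risk_score
    return SpecificMatch(primary_source, primary, ingredients, risk)


# ---------------------------------------------------------------------------
# full enrichment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnrichmentSummary:
    """Coverage of the enrichment run (unique and volume-weighted)."""

    n_unique: int
    frac_unique_matched: float
    frac_total_matched: float
    n_specific_direct: int
    per_source_counts: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "n_unique": self.n_unique,
            "frac_unique_matched": self.frac_unique_matched,
            "frac_total_matched": self.frac_total_matched,
            "n_specific_direct": self.n_specific_direct,
            "per_source_counts": dict(self.per_source_counts),
        }


@dataclass
class EnrichmentResult:
    match_table: pd.DataFrame      # one row per unique product
    line_table: pd.DataFrame       # receipt lines joined to their match
    summary: EnrichmentSummary


def enrich(
    purchases: PurchaseTable,
    generic_db: Sequence[GenericFoodRecord],
    specific_dbs: dict[str, Sequence[SpecificProductRecord]],
    config: EnrichmentConfig | None = None,
) -> EnrichmentResult:
    """Run the full enrichment cascade over a purchase table.

    Unique products are the distinct (item_number, item_name) pairs.
    Pipeline order per product: item-number filter -> GTIN lookup in the
    specific databases -> generic regex matching for GTIN misses.  Products
    matched to a specific database are additionally assigned a generic
    category via their database product name, so the nutrient-comparison
    stage has values from both sources.
    """
    config = config or EnrichmentConfig()
    matcher = GenericMatcher(generic_db, config.weights)
    group_of = {r.category_id: r.group for r in generic_db}
    indexed = index_specific_dbs(specific_dbs)

    df = purchases.df
    volume_col = "quantity" if config.quantity_weighted_volume else None
    uniques = (
        df.assign(_w=df["quantity"] if volume_col else 1)
        .groupby(["item_number", "item_name"], sort=True)
        .agg(n_lines=("item_name", "size"), total_quantity=("_w", "sum"))
        .reset_index()
    )

    # classify each distinct database product name once (specific matches)
    name_class_cache: dict[str, GenericClassification] = {}

    def classify_name(name: str) -> GenericClassification:
        cached = name_class_cache.get(name)
        if cached is None:
            tokens, _ = preprocess_name(name, config.stopwords, config.abbreviations)
            cached = classify_generic(matcher.score(tokens), config.min_score, config.min_margin)
            name_class_cache[name] = cached
        return cached

    rows = []
    for rec in uniques.itertuples(index=False):
        number, name = rec.item_number, rec.item_name
        tokens, attributes = preprocess_name(name, config.stopwords, config.abbreviations)
        norm = normalize_item_number(number)
        flags: set[str] = set()
        gtin = None
        match_source = "unmatched"
        category_id = None
        score = 0.0
        margin = 0.0
        candidates_repr = ""
        risk_score = None
        ingredients: tuple[str, ...] = ()

        specific = None
        if norm.status is ItemNumberStatus.EXCLUDED:
            flags.add(FLAG_EXCLUDED)
        elif norm.is_gtin:
            specific = match_specific(norm.gtin, indexed)

        if specific is not None:
            gtin = norm.gtin
            match_source = f"specific:{specific.source_db}"
            risk_score = specific.risk_score
            ingredients = specific.ingredients
            # secondary generic assignment via the database product name
            name_cls = classify_name(specific.record.product_name)
            category_id = name_cls.category_id
            score = name_cls.score
            margin = name_cls.runner_up_margin
        else:
            ranked = matcher.score(tokens)
            candidates_repr = ";".join(f"{c.category_id}:{c.score:g}" for c in ranked[:3])
            cls = classify_generic(ranked, config.min_score, config.min_margin)
            flags |= cls.flags
            score = cls.score
            margin = cls.runner_up_margin
            if cls.matched:
                match_source = "generic"
                category_id = cls.category_id

        rows.append(
            {
                "item_number_raw": number,
                "item_name_raw": name,
                "match_source": match_source,
                "gtin": gtin or "",
                "category_id": category_id or "",
                "group": group_of.get(category_id, "") if category_id else "",
                "score": score,
                "runner_up_margin": margin,
                "flag_excluded_item_number": FLAG_EXCLUDED in flags,
                "flag_greedy": FLAG_GREEDY in flags,
                "flag_ambiguous": FLAG_AMBIGUOUS in flags,
                "flag_below_threshold": FLAG_BELOW_THRESHOLD in flags,
                "candidates": candidates_repr,
                "weight_g": attributes.get("weight_g"),
                "volume_ml": attributes.get("volume_ml"),
                "pack_count": attributes.get("pack_count"),
                "organic": attributes.get("organic", False),
                "origin": attributes.get("origin", ""),
                "risk_score": risk_score or "",
                "ingredients": ";".join(ingredients),
                "n_lines": rec.n_lines,
                "total_quantity": rec.total_quantity,
            }
        )

    match_table = pd.DataFrame(rows, columns=MATCH_TABLE_COLUMNS)
    if match_table.empty:
        match_table = pd.DataFrame(columns=MATCH_TABLE_COLUMNS)

    line_table = df.merge(
        match_table.rename(
            columns={"item_number_raw": "item_number", "item_name_raw": "item_name"}
        )[
            [
                "item_number",
                "item_name",
                "match_source",
                "gtin",
                "category_id",
                "group",
                "risk_score",
            ]
        ],
        on=["item_number", "item_name"],
        how="left",
    )

    matched = match_table["match_source"] != "unmatched"
    total_volume = match_table["total_quantity"].sum()
    summary = EnrichmentSummary(
        n_unique=len(match_table),
        frac_unique_matched=float(matched.mean()) if len(match_table) else 0.0,
        frac_total_matched=(
            float(match_table.loc[matched, "total_quantity"].sum() / total_volume)
            if total_volume
            else 0.0
        ),
        n_specific_direct=int(match_table["match_source"].str.startswith("specific").sum()),
        per_source_counts=match_table["match_source"].value_counts().to_dict(),
    )
    return EnrichmentResult(match_table=match_table, line_table=line_table, summary=summary)


def export_review_queue(match_table: pd.DataFrame) -> pd.DataFrame:
    """All greedy/ambiguous/unmatched products, highest purchase volume first.

    The queue carries the candidate scores so a reviewer can adjust word
    stems iteratively; nothing in the package mutates patterns itself.
    """
    flagged = match_table[
        match_table["flag_greedy"]
        | match_table["flag_ambiguous"]
        | match_table["flag_below_threshold"]
        | (match_table["match_source"] == "unmatched")
    ]
    return flagged.sort_values(
        ["total_quantity", "item_number_raw", "item_name_raw"],
        ascending=[False, True, True],
    ).reset_index(drop=True)
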