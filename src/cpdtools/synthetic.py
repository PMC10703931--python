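"""Seeded synthetic cohort generator with known ground truth.

Emulates the statistical structure of a multi-retailer digital-receipt
cohort: a Zipf-skewed product catalog built from a brand/type/variant
token vocabulary, a generic food database with regex pattern columns
derived from that vocabulary, partially covering GTIN-keyed specific
databases with log-normally perturbed nutrients (the ground-truth
generator for the nutrient-comparison stage), heterogeneous per-participant
food-group preferences and retailer loyalty (both Dirichlet), retailer
assortments that overlap without being identical (so single-retailer views
systematically miss some groups, e.g. a tobacco-like group carried by few
retailers), noisy abbreviated item names, and inactive months.

Everything is deterministic given (config, seed): one global seed drives
independent per-stage generators derived by fixed offsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .gtin import make_gtin13
from .types import NUTRIENT_COLUMNS, GenericFoodRecord, PurchaseTable, SpecificProductRecord

# fixed stage offsets for sub-generators ------------------------------------
_STAGE_CATALOG = 1
_STAGE_DATABASES = 2
_STAGE_RECEIPTS = 3
_STAGE_NAMES = 4


class CohortConfig(BaseModel):
    """All knobs of the synthetic cohort, with documented defaults.

    Defaults target a desk-scale cohort that preserves the qualitative
    structure of multi-year, multi-retailer receipt data: ~8 shopping trips
    per participant-month, ~10 lines per receipt, 34 retailers, 20 food
    groups plus a few non-food groups, and a product popularity
    distribution skewed toward a small set of frequently bought products.
    """

    model_config = ConfigDict(frozen=True)

    n_participants: int = Field(default=200, ge=1)
    n_retailers: int = Field(default=34, ge=1)
    n_products: int = Field(default=1500, ge=1)
    zipf_exponent: float = Field(default=1.1, gt=0)
    n_food_groups: int = Field(default=20, ge=1)
    n_nonfood_groups: int = Field(default=3, ge=0)
    group_preference_concentration: float = Field(default=2.0, gt=0)
    loyalty_concentration: float = Field(default=0.15, gt=0)
    months: int = Field(default=24, ge=1)
    start_month: str = "2021-01"
    receipts_per_month_mean: float = Field(default=8.4, gt=0)
    lines_per_receipt_mean: float = Field(default=10.0, gt=0)
    specific_db_coverage: float = Field(default=0.6, ge=0, le=1)
    popularity_weighted_coverage: bool = True
    nutrient_noise_sigma: float = Field(default=0.3, ge=0)
    nutrient_missing_prob: float = Field(default=0.05, ge=0, le=1)
    name_noise_level: float = Field(default=0.1, ge=0, le=1)
    inactive_month_prob: float = Field(default=0.1, ge=0, le=1)
    assortment_coverage: float = Field(default=0.9, ge=0, le=1)
    restricted_groups: tuple[str, ...] = ("tobacco",)
    n_carriers_restricted: int = Field(default=8, ge=1)
    internal_code_frac: float = Field(default=0.10, ge=0, le=1)
    excluded_code_frac: float = Field(default=0.02, ge=0, le=1)
    organic_frac: float = Field(default=0.15, ge=0, le=1)
    #: fraction of products whose receipt name is opaque supplier shorthand
    #: (consonant abbreviations + digit codes) that no name pattern can match
    unmatchable_name_frac: float = Field(default=0.12, ge=0, le=1)
    seed: int = 0

    # -- YAML round-trip ----------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        data = self.model_dump()
        data["restricted_groups"] = list(data["restricted_groups"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        return cls(**yaml.safe_load(Path(path).read_text(encoding="utf-8")))


@dataclass
class GroundTruth:
    """Generator-side truth enabling parameter-recovery tests."""

    products: pd.DataFrame      # product_id, item_number, category_id, group, ...
    preferences: pd.DataFrame   # participant_id, group, proportion
    loyalty: pd.DataFrame       # participant_id, retailer_id, proportion

    def group_proportions(self, participant_id: str) -> dict[str, float]:
        sub = self.preferences[self.preferences["participant_id"] == participant_id]
        return dict(zip(sub["group"], sub["proportion"]))

    def product_category(self, item_number: str) -> str:
        sub = self.products[self.products["item_number"] == item_number]
        return str(sub["category_id"].iloc[0])


@dataclass
class CohortData:
    purchases: PurchaseTable
    generic_db: list[GenericFoodRecord]
    specific_dbs: dict[str, list[SpecificProductRecord]]
    truth: GroundTruth
    config: CohortConfig


# ---------------------------------------------------------------------------
# token vocabulary
# ---------------------------------------------------------------------------

# (group key, broad descriptor word, is_food, [(type stem, variant kind, variants)])
# Type stems are globally unique words so word-boundary matching is exact.
_VOCAB: list[tuple[str, str, bool, list[tuple[str, str, list[str]]]]] = [
    ("bread", "bakery", True, [
        ("bread", "specific", ["rye", "wheat", "sourdough", "wholegrain"]),
        ("baguette", "specific", ["classic", "garlic"]),
        ("crispbread", "specific", ["seeded", "plain"]),
        ("rolls", "specific", ["wholegrain", "white"]),
    ]),
    ("milk_products", "dairy", True, [
        ("milk", "fat", ["skimmed", "semi", "whole", "mini"]),
        ("buttermilk", "fat", ["lowfat", "classic"]),
        ("cream", "fat", ["whipping", "sour", "light"]),
        ("yoghurt", "flavor", ["strawberry", "vanilla", "natural"]),
    ]),
    ("cheese", "cheese", True, [
        ("gouda", "fat", ["light", "aged"]),
        ("brie", "fat", ["double", "light"]),
        ("feta", "specific", ["cubes", "block"]),
        ("mozzarella", "specific", ["fresh", "grated"]),
    ]),
    ("vegetables_raw", "produce", True, [
        ("carrots", "specific", ["snack", "bunch"]),
        ("tomatoes", "specific", ["cherry", "plum", "vine"]),
        ("cucumber", "specific", ["long", "mini"]),
        ("lettuce", "specific", ["iceberg", "romaine"]),
        ("onions", "specific", ["yellow", "red"]),
    ]),
    ("fruit", "fruit", True, [
        ("apples", "specific", ["royal", "gala"]),
        ("bananas", "specific", ["fairtrade", "single"]),
        ("oranges", "specific", ["juicing", "navel"]),
        ("grapes", "specific", ["green", "blue"]),
    ]),
    ("red_meat", "meat", True, [
        ("beef", "specific", ["minced", "roast", "steak"]),
        ("pork", "specific", ["chops", "minced", "loin"]),
        ("lamb", "specific", ["leg", "chops"]),
    ]),
    ("poultry", "poultry", True, [
        ("chicken", "specific", ["breast", "thighs", "wings"]),
        ("turkey", "specific", ["breast", "minced"]),
    ]),
    ("fish", "seafood", True, [
        ("salmon", "specific", ["smoked", "fillet"]),
        ("cod", "specific", ["fillet", "loin"]),
        ("tuna", "specific", ["canned", "steak"]),
        ("herring", "specific", ["pickled", "curry"]),
    ]),
    ("alcohol", "alcohol", True, [
        ("beer", "specific", ["pilsner", "lager", "ipa"]),
        ("wine", "specific", ["red", "white", "rose"]),
        ("whisky", "specific", ["malt", "blended"]),
        ("cider", "flavor", ["apple", "pear"]),
    ]),
    ("beverages", "drinks", True, [
        ("cola", "specific", ["zero", "classic"]),
        ("juice", "flavor", ["orange", "apple", "elderflower"]),
        ("coffee", "specific", ["ground", "instant", "beans"]),
        ("tea", "flavor", ["green", "mint", "earl"]),
    ]),
    ("cereals", "breakfast", True, [
        ("oats", "specific", ["rolled", "instant"]),
        ("muesli", "flavor", ["berry", "nut"]),
        ("cornflakes", "specific", ["frosted", "plain"]),
    ]),
    ("pasta_rice", "staples", True, [
        ("pasta", "specific", ["penne", "spaghetti", "fusilli"]),
        ("rice", "specific", ["basmati", "jasmine", "brown"]),
        ("noodles", "specific", ["egg", "instant"]),
    ]),
    ("snacks", "snacks", True, [
        ("chips", "flavor", ["salted", "paprika", "nacho"]),
        ("popcorn", "flavor", ["sweet", "salted"]),
        ("crackers", "specific", ["salted", "sesame"]),
    ]),
    ("sweets", "confectionery", True, [
        ("chocolate", "specific", ["dark", "white", "mint"]),
        ("licorice", "specific", ["salty", "sweet"]),
        ("biscuits", "specific", ["digestive", "butter"]),
    ]),
    ("frozen", "frozen", True, [
        ("pizza", "flavor", ["pepperoni", "margherita"]),
        ("icecream", "flavor", ["vanilla", "strawberry"]),
        ("peas", "specific", ["frozen", "petits"]),
    ]),
    ("eggs", "eggs", True, [
        ("eggs", "specific", ["freerange", "barn", "large"]),
    ]),
    ("spreads", "spreads", True, [
        ("jam", "flavor", ["strawberry", "raspberry"]),
        ("honey", "specific", ["acacia", "forest"]),
        ("peanutbutter", "specific", ["crunchy", "smooth"]),
    ]),
    ("condiments", "condiments", True, [
        ("ketchup", "specific", ["classic", "spicy"]),
        ("mustard", "specific", ["dijon", "coarse"]),
        ("mayonnaise", "specific", ["classic", "light"]),
    ]),
    ("oils", "pantry", True, [
        ("oliveoil", "specific", ["virgin", "mild"]),
        ("rapeseedoil", "specific", ["cold", "refined"]),
        ("vinegar", "specific", ["balsamic", "apple"]),
    ]),
    ("legumes_nuts", "nuts", True, [
        ("beans", "specific", ["kidney", "black"]),
        ("lentils", "specific", ["red", "green"]),
        ("almonds", "specific", ["roasted", "raw"]),
        ("peanuts", "specific", ["salted", "roasted"]),
    ]),
    ("tobacco", "tobacco", False, [
        ("cigarettes", "specific", ["filter", "menthol"]),
        ("snus", "specific", ["strong", "mild"]),
    ]),
    ("cleaning", "cleaning", False, [
        ("detergent", "specific", ["color", "liquid"]),
        ("dishsoap", "specific", ["lemon", "sensitive"]),
        ("bleach", "specific", ["classic", "gel"]),
    ]),
    ("personal_care", "care", False, [
        ("shampoo", "specific", ["mild", "repair"]),
        ("toothpaste", "specific", ["mint", "whitening"]),
        ("deodorant", "specific", ["roll", "spray"]),
        ("soap", "specific", ["liquid", "bar"]),
    ]),
]

_BRANDS = [
    "nordvang", "havgaard", "solmark", "birkely", "dalfrisk", "kystens",
    "agerlund", "fjordblik", "stenbro", "lindholm", "gronbo", "mollegaard",
]

_UNIT_TOKENS = [
    "500g", "1kg", "250g", "200g", "1l", "500ml", "330ml", "6-pack", "4-pack", "10-stk",
]

_CHEMLIKE_GROUPS = {"cleaning", "personal_care"}


def _build_vocab(config: CohortConfig) -> list[tuple[str, str, bool, list]]:
    """Select/extend the vocabulary to the configured group counts."""
    food = [g for g in _VOCAB if g[2]]
    nonfood = [g for g in _VOCAB if not g[2]]
    out = list(food[: config.n_food_groups])
    for i in range(len(food), config.n_food_groups):  # synthesize extras if asked
        stem = f"foodtype{i}"
        out.append(
            (f"foodgroup{i}", f"foodword{i}", True,
             [(f"{stem}{chr(97 + j)}", "specific", ["alpha", "beta"]) for j in range(3)])
        )
    out.extend(nonfood[: config.n_nonfood_groups])
    for i in range(len(nonfood), config.n_nonfood_groups):
        out.append(
            (f"nonfoodgroup{i}", f"nonfoodword{i}", False,
             [(f"nonfoodtype{i}{chr(97 + j)}", "specific", ["alpha", "beta"]) for j in range(2)])
        )
    return out


def _category_table(config: CohortConfig) -> pd.DataFrame:
    rows = []
    for group, group_word, is_food, types in _build_vocab(config):
        for stem, kind, variants in types:
            for variant in variants:
                rows.append(
                    {
                        "category_id": f"{stem}_{variant}".replace(" ", ""),
                        "category_name": f"{stem.capitalize()}, {variant}",
                        "group": group,
                        "group_word": group_word,
                        "is_food": is_food,
                        "stem": stem,
                        "variant_kind": kind,
                        "variant": variant,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stage 1: catalog
# ---------------------------------------------------------------------------


def generate_catalog(config: CohortConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the product catalog and (partial) ground truth.

    Each product gets a valid GTIN-13 (or a supplier-internal / excluded
    short code for configured fractions), a clean canonical name built from
    (organic marker, brand, type stem, variant, pack-size) tokens, a true
    category with true per-100 g nutrients, and a Zipf popularity weight.
    """
    rng = np.random.default_rng([_STAGE_CATALOG, config.seed])
    cats = _category_table(config)
    n = config.n_products

    cat_idx = rng.integers(0, len(cats), n)
    brand_idx = rng.integers(0, len(_BRANDS), n)
    unit_idx = rng.integers(0, len(_UNIT_TOKENS), n)
    organic = (rng.random(n) < config.organic_frac) & cats["is_food"].to_numpy()[cat_idx]

    # item numbers: GTIN by default; configured fractions get internal or
    # too-short codes (the latter exercise the exclusion rule)
    u = rng.random(n)
    item_numbers = []
    n_excluded = 0
    for i in range(n):
        if u[i] < config.excluded_code_frac:
            # outside the 3..14-digit window; 2-digit codes first, then
            # 15-digit ones so every item number stays globally unique
            if n_excluded < 90:
                item_numbers.append(str(10 + n_excluded))
            else:
                item_numbers.append(str(10**14 + i))
            n_excluded += 1
        elif u[i] < config.excluded_code_frac + config.internal_code_frac:
            item_numbers.append(str(20000 + i))              # internal, name-match only
        else:
            item_numbers.append(make_gtin13(f"570{i:09d}"))

    opaque = rng.random(n) < config.unmatchable_name_frac
    names = []
    for i in range(n):
        c = cats.iloc[cat_idx[i]]
        if opaque[i]:
            # supplier shorthand: brand initials + consonant-stripped stem + code
            stem_abbr = c["stem"][0] + "".join(
                ch for ch in c["stem"][1:] if ch not in "aeiouy"
            )[:3]
            names.append(
                f"{_BRANDS[brand_idx[i]][:2]} {stem_abbr} {rng.integers(100, 9999)}"
            )
            continue
        parts = []
        if organic[i]:
            parts.append("øko")
        parts.extend([_BRANDS[brand_idx[i]], c["stem"], c["variant"], _UNIT_TOKENS[unit_idx[i]]])
        names.append(" ".join(parts))

    # Zipf popularity over a random rank permutation
    ranks = rng.permutation(n) + 1
    weights = ranks.astype(float) ** -config.zipf_exponent
    weights /= weights.sum()

    # prices in integer ore, lognormal around ~20 DKK
    price_ore = np.rint(np.exp(rng.normal(np.log(2000), 0.5, n))).astype(np.int64)
    price_ore = np.clip(price_ore, 100, 60000)

    products = pd.DataFrame(
        {
            "product_id": np.arange(n),
            "item_number": item_numbers,
            "canonical_name": names,
            "category_id": cats["category_id"].to_numpy()[cat_idx],
            "group": cats["group"].to_numpy()[cat_idx],
            "is_food": cats["is_food"].to_numpy()[cat_idx],
            "brand": np.array(_BRANDS)[brand_idx],
            "popularity_weight": weights,
            "unit_price_ore": price_ore,
            "organic": organic,
        }
    )
    truth = GroundTruth(products=products, preferences=pd.DataFrame(), loyalty=pd.DataFrame())
    return products, truth


# ---------------------------------------------------------------------------
# stage 2: databases
# ---------------------------------------------------------------------------


def _category_nutrients(cats: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """True per-100 g nutrients per category (zeros for non-food)."""
    n = len(cats)
    energy = np.exp(rng.normal(np.log(800), 0.7, n)).clip(50, 3800)
    total_g = rng.uniform(5, 90, n)
    split = rng.dirichlet([1.0, 1.0, 1.0], n)
    out = pd.DataFrame(
        {
            "category_id": cats["category_id"],
            "energy_kj": np.round(energy, 1),
            "fat_g": np.round(total_g * split[:, 0], 2),
            "protein_g": np.round(total_g * split[:, 1], 2),
            "carbohydrate_g": np.round(total_g * split[:, 2], 2),
        }
    )
    nonfood = ~cats["is_food"].to_numpy()
    out.loc[nonfood, NUTRIENT_COLUMNS] = 0.0
    return out


def generate_databases(
    products: pd.DataFrame,
    truth: GroundTruth,
    config: CohortConfig,
) -> tuple[list[GenericFoodRecord], dict[str, list[SpecificProductRecord]]]:
    """Build the generic DB (with regex columns) and the specific DBs.

    The generic DB has one record per true category, with patterns built
    from the vocabulary tokens used in canonical names.  Each specific DB
    contains a fraction ``specific_db_coverage`` of its eligible products
    (popularity-weighted inclusion when configured), with nutrients
    perturbed multiplicatively by log-normal noise of the configured sigma
    — the ground truth for the nutrient-comparison stage.
    """
    rng = np.random.default_rng([_STAGE_DATABASES, config.seed])
    cats = _category_table(config)
    nutrients = _category_nutrients(cats, rng).set_index("category_id")

    brands_per_cat = products.groupby("category_id")["brand"].agg(lambda s: sorted(set(s)))

    generic: list[GenericFoodRecord] = []
    for rec in cats.to_dict(orient="records"):
        cid = rec["category_id"]
        brands = brands_per_cat.get(cid, [])
        patterns = {
            "pattern_type": rec["stem"],
            "pattern_generic": rec["group_word"],
            "pattern_brand": "|".join(brands),
            "pattern_specific": "",
            "pattern_flavor": "",
            "pattern_fat": "",
        }
        kind_col = {"specific": "pattern_specific", "flavor": "pattern_flavor", "fat": "pattern_fat"}
        patterns[kind_col[rec["variant_kind"]]] = rec["variant"]
        generic.append(
            GenericFoodRecord(
                category_id=cid,
                category_name=rec["category_name"],
                group=rec["group"],
                is_food=bool(rec["is_food"]),
                nutrients=nutrients.loc[cid, NUTRIENT_COLUMNS].to_dict(),
                **patterns,
            )
        )

    gtin_mask = products["item_number"].str.len() == 13
    eligible = {
        "gs1like": products[gtin_mask],
        "offlike": products[gtin_mask & products["is_food"]],
        "chemlike": products[gtin_mask & products["group"].isin(_CHEMLIKE_GROUPS)],
    }

    specific_dbs: dict[str, list[SpecificProductRecord]] = {}
    for source, pool in eligible.items():
        k = int(round(config.specific_db_coverage * len(pool)))
        if k == 0 or pool.empty:
            specific_dbs[source] = []
            continue
        if config.popularity_weighted_coverage:
            p = pool["popularity_weight"].to_numpy()
            p = p / p.sum()
            chosen = rng.choice(len(pool), size=min(k, len(pool)), replace=False, p=p)
        else:
            chosen = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
        records = []
        for row in pool.iloc[np.sort(chosen)].to_dict(orient="records"):
            base = nutrients.loc[row["category_id"], NUTRIENT_COLUMNS]
            noise = np.exp(rng.normal(0.0, config.nutrient_noise_sigma, len(NUTRIENT_COLUMNS)))
            values = {}
            if row["is_food"]:
                for j, col in enumerate(NUTRIENT_COLUMNS):
                    if rng.random() >= config.nutrient_missing_prob:
                        values[col] = float(np.round(base[col] * noise[j], 3))
            risk = rng.choice(["A", "B", "C"]) if source == "chemlike" else None
            records.append(
                SpecificProductRecord(
                    gtin=row["item_number"],
                    product_name=row["canonical_name"],
                    nutrients=values,
                    ingredients=(row["brand"], row["category_id"].split("_")[0]),
                    risk_score=risk,
                    source_db=source,
                )
            )
        specific_dbs[source] = records
    return generic, specific_dbs


# ---------------------------------------------------------------------------
# stage 3: receipts
# ---------------------------------------------------------------------------


def _corrupt_name(parts: list[str], rng: np.random.Generator) -> str:
    """Apply one receipt-style corruption: abbreviation (vowel dropping),
    truncation to <= 20 characters, unit-token injection, or case mangling."""
    parts = list(parts)
    op = rng.integers(0, 4)
    if op == 0:  # vowel-drop the type-stem token (index 1 or 2)
        idx = min(1, len(parts) - 1)
        for i, tok in enumerate(parts):
            if len(tok) > 3 and not tok[0].isdigit() and i > 0:
                idx = i
                break
        tok = parts[idx]
        parts[idx] = tok[0] + "".join(ch for ch in tok[1:] if ch not in "aeiouyæøå")
        return " ".join(parts)
    if op == 1:  # hard truncation
        return " ".join(parts)[:20].rstrip()
    if op == 2:  # stray unit token
        return " ".join(parts) + " " + str(rng.choice(_UNIT_TOKENS))
    return " ".join(p.upper() if rng.random() < 0.5 else p for p in parts)  # case mangle


def _display_names(products: pd.DataFrame, config: CohortConfig) -> np.ndarray:
    """Per-product display name: canonical, or corrupted with probability
    ``name_noise_level`` (one fixed variant per product)."""
    rng = np.random.default_rng([_STAGE_NAMES, config.seed])
    names = products["canonical_name"].to_numpy().copy()
    corrupt = rng.random(len(names)) < config.name_noise_level
    for i in np.flatnonzero(corrupt):
        names[i] = _corrupt_name(names[i].split(), rng)
    return names


def _participant_truth(config: CohortConfig, groups: list[str], is_food: dict[str, bool]):
    """Dirichlet preferences over groups (non-food downweighted) and
    Dirichlet loyalty over retailers, per participant."""
    rng = np.random.default_rng([_STAGE_RECEIPTS, config.seed])
    alpha_groups = np.array(
        [config.group_preference_concentration * (1.0 if is_food[g] else 0.25) for g in groups]
    )
    prefs = rng.dirichlet(alpha_groups, config.n_participants)
    loyalty = rng.dirichlet(
        np.full(config.n_retailers, config.loyalty_concentration), config.n_participants
    )
    return prefs, loyalty


def _assortments(config: CohortConfig, products: pd.DataFrame) -> np.ndarray:
    """Retailer x product carry matrix.

    Retailers carry a random ``assortment_coverage`` fraction of the
    catalog; restricted groups are carried only by a fixed subset of
    ``n_carriers_restricted`` retailers.  Every product has >= 1 carrier.
    """
    rng = np.random.default_rng([_STAGE_RECEIPTS, config.seed, 999])
    n_r, n_p = config.n_retailers, len(products)
    carry = rng.random((n_r, n_p)) < config.assortment_coverage
    restricted = products["group"].isin(config.restricted_groups).to_numpy()
    restricted_carriers = np.arange(n_r)
    if restricted.any() and n_r > config.n_carriers_restricted:
        restricted_carriers = rng.choice(n_r, size=config.n_carriers_restricted, replace=False)
        non_carriers = np.setdiff1d(np.arange(n_r), restricted_carriers)
        carry[np.ix_(non_carriers, np.flatnonzero(restricted))] = False
    orphan = ~carry.any(axis=0)
    for j in np.flatnonzero(orphan):
        pool = restricted_carriers if restricted[j] else np.arange(n_r)
        carry[rng.choice(pool), j] = True
    return carry


def generate_receipts(
    products: pd.DataFrame,
    truth: GroundTruth,
    config: CohortConfig,
) -> tuple[PurchaseTable, GroundTruth]:
    """Simulate the receipt stream and complete the ground truth.

    Per participant-month (unless inactive): a Poisson number of shopping
    trips on distinct days and a Poisson total line count.  Each line
    samples a food group from the participant's true preference vector
    (so per-participant group frequencies converge to the truth), then a
    product within the group by Zipf weight restricted to the trip
    retailer's assortment.  The trip retailer is drawn from the
    participant's loyalty vector; only when it carries no product of the
    sampled group at all (e.g. a tobacco-like restricted group) does the
    line detour to a loyalty-weighted retailer that does, producing the
    occasional same-day second receipt.
    """
    groups = sorted(products["group"].unique())
    is_food = dict(zip(products["group"], products["is_food"]))
    prefs, loyalty = _participant_truth(config, groups, is_food)
    carry = _assortments(config, products)
    display = _display_names(products, config)

    group_products = {
        g: np.flatnonzero((products["group"] == g).to_numpy()) for g in groups
    }
    pop = products["popularity_weight"].to_numpy()

    # per (retailer, group): carried products with cumulative Zipf weights
    n_r = config.n_retailers
    group_avail = np.zeros((n_r, len(groups)), dtype=bool)
    rg_products: list[list[tuple[np.ndarray, np.ndarray] | None]] = []
    for r in range(n_r):
        per_group = []
        for gi, g in enumerate(groups):
            idx = group_products[g][carry[r, group_products[g]]]
            if len(idx):
                w = pop[idx]
                per_group.append((idx, np.cumsum(w) / w.sum()))
                group_avail[r, gi] = True
            else:
                per_group.append(None)
        rg_products.append(per_group)

    item_numbers = products["item_number"].to_numpy()
    price_ore = products["unit_price_ore"].to_numpy()
    start = pd.Period(config.start_month, freq="M")
    month_periods = [start + m for m in range(config.months)]

    frames = []
    for pidx in range(config.n_participants):
        rng = np.random.default_rng([_STAGE_RECEIPTS, config.seed, pidx])
        p_prefs = prefs[pidx]
        p_loyalty = loyalty[pidx]
        all_month, all_day, all_gidx, all_ret = [], [], [], []
        for m in range(config.months):
            if rng.random() < config.inactive_month_prob:
                continue
            k = max(1, int(rng.poisson(config.receipts_per_month_mean)))
            k = min(k, 28)
            days = rng.choice(28, size=k, replace=False) + 1
            n_lines = int(rng.poisson(k * config.lines_per_receipt_mean))
            if n_lines == 0:
                continue
            trip_of_line = rng.integers(0, k, n_lines)
            trip_retailer = rng.choice(n_r, size=k, p=p_loyalty)
            gidx = rng.choice(len(groups), size=n_lines, p=p_prefs)
            ret = trip_retailer[trip_of_line]
            needs_detour = ~group_avail[ret, gidx]
            if needs_detour.any():
                fb = np.flatnonzero(needs_detour)
                w = p_loyalty[:, None] * group_avail[:, gidx[fb]]
                with np.errstate(divide="ignore"):
                    logw = np.log(w)
                gumbel = rng.gumbel(size=logw.shape)
                ret[fb] = np.argmax(logw + gumbel, axis=0)
            all_month.append(np.full(n_lines, m))
            all_day.append(days[trip_of_line])
            all_gidx.append(gidx)
            all_ret.append(ret)
        if not all_month:
            continue
        month = np.concatenate(all_month)
        day = np.concatenate(all_day)
        gidx = np.concatenate(all_gidx)
        ret = np.concatenate(all_ret)
        n = len(month)

        # products per line: Zipf within the group, restricted to the
        # (possibly detoured-to) retailer's assortment
        prod = np.empty(n, dtype=np.int64)
        pair_key = ret * len(groups) + gidx
        for key in np.unique(pair_key):
            mask = pair_key == key
            idx, cum = rg_products[int(key) // len(groups)][int(key) % len(groups)]
            prod[mask] = idx[np.searchsorted(cum, rng.random(int(mask.sum())))]

        # one timestamp per receipt (= distinct month/day/retailer triple)
        key = month * 100000 + day * 1000 + ret
        uniq, inverse = np.unique(key, return_inverse=True)
        hours = rng.integers(8, 22, len(uniq))
        minutes = rng.integers(0, 60, len(uniq))
        ts = np.array(
            [
                (month_periods[k_ // 100000].to_timestamp()
                 + pd.Timedelta(days=int(k_ // 1000 % 100) - 1, hours=int(h), minutes=int(mi)))
                for k_, h, mi in zip(uniq, hours, minutes)
            ],
            dtype="datetime64[ns]",
        )

        quantity = 1 + rng.poisson(0.35, n)
        price = price_ore[prod]
        disc = np.zeros(n, dtype=np.int64)
        dmask = rng.random(n) < 0.1
        disc[dmask] = np.floor(
            price[dmask] * quantity[dmask] * rng.uniform(0.1, 0.3, int(dmask.sum()))
        ).astype(np.int64)

        frames.append(
            pd.DataFrame(
                {
                    "participant_id": f"P{pidx:04d}",
                    "retailer_id": np.char.add("R", np.char.zfill(ret.astype(str), 2)),
                    "purchase_datetime": ts[inverse],
                    "item_number": item_numbers[prod],
                    "item_name": display[prod],
                    "unit_price_ore": price,
                    "quantity": quantity.astype(np.int64),
                    "discount_ore": disc,
                }
            )
        )

    if frames:
        df = pd.concat(frames, ignore_index=True)
        df = df.sort_values(
            ["participant_id", "purchase_datetime", "retailer_id"], kind="stable"
        ).reset_index(drop=True)
        purchases = PurchaseTable(df, validate=False)
    else:
        purchases = PurchaseTable.empty()

    participant_ids = [f"P{p:04d}" for p in range(config.n_participants)]
    pref_df = pd.DataFrame(
        [
            {"participant_id": pid, "group": g, "proportion": prefs[i, j]}
            for i, pid in enumerate(participant_ids)
            for j, g in enumerate(groups)
        ]
    )
    loyalty_df = pd.DataFrame(
        [
            {"participant_id": pid, "retailer_id": f"R{r:02d}", "proportion": loyalty[i, r]}
            for i, pid in enumerate(participant_ids)
            for r in range(config.n_retailers)
        ]
    )
    full_truth = GroundTruth(products=truth.products, preferences=pref_df, loyalty=loyalty_df)
    return purchases, full_truth


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def generate_cohort(config: CohortConfig, out_dir: str | Path | None = None) -> CohortData:
    """Compose catalog, databases and receipts; optionally write all outputs."""
    products, truth0 = generate_catalog(config)
    generic_db, specific_dbs = generate_databases(products, truth0, config)
    purchases, truth = generate_receipts(products, truth0, config)
    data = CohortData(
        purchases=purchases,
        generic_db=generic_db,
        specific_dbs=specific_dbs,
        truth=truth,
        config=config,
    )
    if out_dir is not None:
        write_cohort(data, out_dir)
    return data


def write_cohort(data: CohortData, out_dir: str | Path) -> dict[str, str]:
    """Write all cohort artifacts as flat files; returns the file manifest."""
    from . import io as cio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}
    cio.write_receipts(data.purchases, out / "receipts.jsonl")
    manifest["receipts"] = str(out / "receipts.jsonl")
    cio.write_generic_db(data.generic_db, out / "generic_db.csv")
    manifest["generic_db"] = str(out / "generic_db.csv")
    for source, records in data.specific_dbs.items():
        path = out / f"specific_{source}.csv"
        cio.write_specific_db(records, path)
        manifest[f"specific_{source}"] = str(path)
    cio.write_table(data.truth.products, out / "truth_products.csv", "csv")
    cio.write_table(data.truth.preferences, out / "truth_preferences.csv", "csv")
    cio.write_table(data.truth.loyalty, out / "truth_loyalty.csv", "csv")
    data.config.to_yaml(out / "cohort_config.yaml")
    manifest.update(
        truth_products=str(out / "truth_products.csv"),
        truth_preferences=str(out / "truth_preferences.csv"),
        truth_loyalty=str(out / "truth_loyalty.csv"),
        config=str(out / "cohort_config.yaml"),
    )
    return manifest
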