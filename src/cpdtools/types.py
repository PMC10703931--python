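"""Domain types shared by every pipeline stage.

A receipt line is the atomic observation: one purchased item on one
receipt.  A receipt is implicitly the set of lines sharing a
(participant_id, retailer_id, purchase_datetime) triple.  Currency is
held internally as integer ore (1/100 DKK) so spend summaries are exact
and order-independent; the on-disk formats use decimal DKK.
"""

from __future__ import annotations

import re
from datetime import datetime
from typing import Iterable, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

#: Internal column order for purchase tables (currency in integer ore).
RECEIPT_COLUMNS = [
    "participant_id",
    "retailer_id",
    "purchase_datetime",
    "item_number",
    "item_name",
    "unit_price_ore",
    "quantity",
    "discount_ore",
]

#: On-disk header for receipts (currency in decimal DKK).
RECEIPT_FILE_COLUMNS = [
    "participant_id",
    "retailer_id",
    "purchase_datetime",
    "item_number",
    "item_name",
    "unit_price_dkk",
    "quantity",
    "discount_dkk",
]

NUTRIENT_COLUMNS = ["energy_kj", "fat_g", "protein_g", "carbohydrate_g"]

PATTERN_COLUMNS = [
    "pattern_brand",
    "pattern_type",
    "pattern_specific",
    "pattern_generic",
    "pattern_flavor",
    "pattern_fat",
]

SPECIFIC_SOURCES = ("gs1like", "chemlike", "offlike")


class ReceiptLine(BaseModel):
    """One purchased item on one receipt."""

    model_config = ConfigDict(frozen=True)

    participant_id: str
    retailer_id: str
    purchase_datetime: datetime
    item_number: str
    item_name: str
    unit_price_ore: int
    quantity: int
    discount_ore: int = 0

    @field_validator("item_name")
    @classmethod
    def _name_nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("item_name must be non-empty")
        return v

    @field_validator("quantity")
    @classmethod
    def _qty_positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("quantity must be >= 1")
        return v

    @field_validator("unit_price_ore", "discount_ore")
    @classmethod
    def _nonnegative(cls, v: int) -> int:
        if v < 0:
            raise ValueError("currency amounts must be >= 0")
        return v

    @model_validator(mode="after")
    def _discount_bounded(self) -> "ReceiptLine":
        if self.discount_ore > self.quantity * self.unit_price_ore:
            raise ValueError("discount exceeds quantity * unit_price")
        return self


class GenericFoodRecord(BaseModel):
    """A mutually exclusive generic food (or custom non-food) category.

    Carries per-100 g nutrient values and the regex pattern columns used by
    the name-matching score, plus a coarser ``group`` label (the food-group
    layer used by the retailer-coverage and evaluation stages).
    """

    model_config = ConfigDict(frozen=True)

    category_id: str
    category_name: str
    group: str
    is_food: bool
    nutrients: dict[str, float]
    pattern_brand: str = ""
    pattern_type: str = ""
    pattern_specific: str = ""
    pattern_generic: str = ""
    pattern_flavor: str = ""
    pattern_fat: str = ""

    @field_validator("nutrients")
    @classmethod
    def _nutrients_nonnegative(cls, v: dict[str, float]) -> dict[str, float]:
        for name, value in v.items():
            if pd.notna(value) and value < 0:
                raise ValueError(f"nutrient {name} is negative")
        return v

    @model_validator(mode="after")
    def _patterns_compile(self) -> "GenericFoodRecord":
        for col in PATTERN_COLUMNS:
            pat = getattr(self, col)
            if pat:
                try:
                    re.compile(pat)
                except re.error as exc:
                    raise ValueError(
                        f"category {self.category_id}: column {col} does not compile: {exc}"
                    ) from exc
        return self


class SpecificProductRecord(BaseModel):
    """A GTIN-keyed branded product from a specific product database."""

    model_config = ConfigDict(frozen=True)

    gtin: str
    product_name: str
    nutrients: dict[str, float]
    ingredients: tuple[str, ...] = ()
    risk_score: Optional[str] = None
    source_db: str
    gtin_valid: bool = True

    @field_validator("risk_score")
    @classmethod
    def _risk_in_abc(cls, v: Optional[str]) -> Optional[str]:
        if v is not None and v not in {"A", "B", "C"}:
            raise ValueError("risk_score must be one of A, B, C")
        return v

    @field_validator("source_db")
    @classmethod
    def _known_source(cls, v: str) -> str:
        if v not in SPECIFIC_SOURCES:
            raise ValueError(f"source_db must be one of {SPECIFIC_SOURCES}")
        return v

    @model_validator(mode="after")
    def _risk_only_chemlike(self) -> "SpecificProductRecord":
        if self.risk_score is not None and self.source_db != "chemlike":
            raise ValueError("risk_score is only defined for chemlike records")
        return self


class PurchaseTable:
    """An ordered collection of receipt lines backed by a DataFrame.

    Receipts are the distinct (participant_id, retailer_id,
    purchase_datetime) triples; grouping is a pure function of those keys.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = [c for c in RECEIPT_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        df = df[RECEIPT_COLUMNS].reset_index(drop=True)
        df = df.astype(
            {
                "participant_id": str,
                "retailer_id": str,
                "item_number": str,
                "item_name": str,
                "unit_price_ore": "int64",
                "quantity": "int64",
                "discount_ore": "int64",
            }
        )
        if df["purchase_datetime"].dtype == object:
            df["purchase_datetime"] = pd.to_datetime(df["purchase_datetime"], format="ISO8601")
        else:
            df["purchase_datetime"] = pd.to_datetime(df["purchase_datetime"])
        if validate:
            _validate_lines(df)
        self.df = df

    # -- construction -------------------------------------------------
    @classmethod
    def from_lines(cls, lines: Iterable[ReceiptLine]) -> "PurchaseTable":
        rows = [line.model_dump() for line in lines]
        df = pd.DataFrame(rows, columns=RECEIPT_COLUMNS)
        return cls(df, validate=False)  # pydantic already validated

    @classmethod
    def empty(cls) -> "PurchaseTable":
        return cls(pd.DataFrame(columns=RECEIPT_COLUMNS), validate=False)

    # -- views ---------------------------------------------------------
    def to_lines(self) -> list[ReceiptLine]:
        return [
            ReceiptLine(**rec)
            for rec in self.df.to_dict(orient="records")
        ]

    @property
    def n_lines(self) -> int:
        return len(self.df)

    @property
    def n_receipts(self) -> int:
        if self.df.empty:
            return 0
        return len(
            self.df[["participant_id", "retailer_id", "purchase_datetime"]].drop_duplicates()
        )

    def receipt_keys(self) -> pd.DataFrame:
        return self.df[["participant_id", "retailer_id", "purchase_datetime"]].drop_duplicates()

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PurchaseTable):
            return NotImplemented
        return self.df.equals(other.df)

    def __repr__(self) -> str:
        return f"PurchaseTable({self.n_lines} lines, {self.n_receipts} receipts)"


class SchemaError(ValueError):
    """A tabular input does not match the documented schema."""


class RowValidationError(ValueError):
    """A row violates a domain invariant; carries the offending row number."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


def _validate_lines(df: pd.DataFrame) -> None:
    """Vectorized invariant checks, reporting the first offending row."""
    checks = [
        (df["quantity"] < 1, "quantity must be >= 1"),
        (df["unit_price_ore"] < 0, "unit_price must be >= 0"),
        (df["discount_ore"] < 0, "discount must be >= 0"),
        (
            df["discount_ore"] > df["quantity"] * df["unit_price_ore"],
            "discount exceeds quantity * unit_price",
        ),
        (df["item_name"].str.strip() == "", "item_name must be non-empty"),
        (df["purchase_datetime"].isna(), "unparseable purchase_datetime"),
    ]
    for mask, message in checks:
        if mask.any():
            raise RowValidationError(int(mask.idxmax()), message)
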