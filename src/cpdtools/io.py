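"""Readers and writers for the flat interchange formats.

JSON-lines is the canonical interchange (one receipt line per record);
CSV is supported with the same documented header.  Currency columns are
decimal DKK on disk and integer ore in memory, so round-trips are exact
at two decimals.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .gtin import normalize_item_number
from .types import (
    NUTRIENT_COLUMNS,
    PATTERN_COLUMNS,
    RECEIPT_FILE_COLUMNS,
    GenericFoodRecord,
    PurchaseTable,
    SchemaError,
    SpecificProductRecord,
)

_FORMATS = ("csv", "jsonl")


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise ValueError(f"format must be one of {_FORMATS}")
        return fmt
    suffix = Path(path).suffix.lower()
    return "jsonl" if suffix in {".jsonl", ".ndjson", ".json"} else "csv"


def read_receipts(path: str | Path, format: str | None = None) -> PurchaseTable:
    """Read a receipt-line table (CSV or JSON-lines) into a PurchaseTable.

    Raises :class:`SchemaError` if a documented column is missing and
    :class:`RowValidationError` (with the row number) on the first
    invariant violation.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        df = pd.read_csv(
            path,
            dtype={
                "participant_id": str,
                "retailer_id": str,
                "item_number": str,
                "item_name": str,
            },
            keep_default_na=False,
            na_values=[],
        )
    else:
        df = pd.read_json(path, lines=True, dtype={"item_number": str})
        if df.empty:
            df = pd.DataFrame(columns=RECEIPT_FILE_COLUMNS)
    missing = [c for c in RECEIPT_FILE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"receipts file {path}: missing column(s) {', '.join(missing)}")
    out = df[RECEIPT_FILE_COLUMNS].copy()
    out["unit_price_ore"] = _dkk_to_ore(out.pop("unit_price_dkk"))
    out["discount_ore"] = _dkk_to_ore(out.pop("discount_dkk"))
    out["quantity"] = pd.to_numeric(out["quantity"]).astype("int64")
    return PurchaseTable(out)


def _dkk_to_ore(series: pd.Series) -> pd.Series:
    return np.rint(pd.to_numeric(series) * 100).astype("int64")


def _ore_to_dkk(series: pd.Series) -> pd.Series:
    return series.astype("int64") / 100.0


def purchase_table_to_file_frame(table: PurchaseTable) -> pd.DataFrame:
    """External representation of a PurchaseTable (decimal DKK columns)."""
    df = table.df.copy()
    df["unit_price_dkk"] = _ore_to_dkk(df.pop("unit_price_ore"))
    df["discount_dkk"] = _ore_to_dkk(df.pop("discount_ore"))
    df["purchase_datetime"] = df["purchase_datetime"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    return df[RECEIPT_FILE_COLUMNS]


def write_receipts(table: PurchaseTable, path: str | Path, format: str | None = None) -> None:
    write_table(purchase_table_to_file_frame(table), path, format)


def write_table(records: pd.DataFrame, path: str | Path, format: str | None = None) -> None:
    """Write any tabular result as CSV or JSON-lines.

    Floats are written with up to 10 significant digits, enough for all
    nutrient/currency precision used in the pipeline; strings and integers
    round-trip bit-exactly.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        records.to_csv(path, index=False, float_format="%.10g")
    else:
        with open(path, "w", encoding="utf-8") as fh:
            for rec in records.to_dict(orient="records"):
                fh.write(json.dumps(_jsonable(rec), ensure_ascii=False) + "\n")


def _jsonable(rec: dict) -> dict:
    out = {}
    for key, value in rec.items():
        if isinstance(value, (np.integer,)):
            value = int(value)
        elif isinstance(value, (np.floating,)):
            value = float(value)
        elif isinstance(value, pd.Timestamp):
            value = value.isoformat()
        elif isinstance(value, np.bool_):
            value = bool(value)
        out[key] = value
    return out


# ---------------------------------------------------------------------------
# product databases
# ---------------------------------------------------------------------------

_GENERIC_BASE_COLUMNS = ["category_id", "category_name", "group", "is_food"]


def read_generic_db(path: str | Path) -> list[GenericFoodRecord]:
    """Read the generic (Frida-like) food database CSV.

    Every pattern column must compile and category ids must be unique;
    violations raise :class:`SchemaError` naming the category and column.
    """
    df = pd.read_csv(Path(path), keep_default_na=False, na_values=[""])
    missing = [
        c
        for c in _GENERIC_BASE_COLUMNS + NUTRIENT_COLUMNS + PATTERN_COLUMNS
        if c not in df.columns
    ]
    if missing:
        raise SchemaError(f"generic DB {path}: missing column(s) {', '.join(missing)}")
    dupes = df["category_id"][df["category_id"].duplicated()]
    if not dupes.empty:
        raise SchemaError(f"generic DB {path}: duplicate category_id {dupes.iloc[0]!r}")
    records = []
    for rec in df.to_dict(orient="records"):
        nutrients = {c: float(rec[c]) if pd.notna(rec[c]) else float("nan") for c in NUTRIENT_COLUMNS}
        patterns = {c: "" if pd.isna(rec[c]) else str(rec[c]) for c in PATTERN_COLUMNS}
        try:
            records.append(
                GenericFoodRecord(
                    category_id=str(rec["category_id"]),
                    category_name=str(rec["category_name"]),
                    group=str(rec["group"]),
                    is_food=_as_bool(rec["is_food"]),
                    nutrients=nutrients,
                    **patterns,
                )
            )
        except ValueError as exc:
            raise SchemaError(f"generic DB {path}: {exc}") from exc
    return records


def generic_db_to_frame(records: list[GenericFoodRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "category_id": r.category_id,
            "category_name": r.category_name,
            "group": r.group,
            "is_food": r.is_food,
        }
        row.update({c: r.nutrients.get(c, float("nan")) for c in NUTRIENT_COLUMNS})
        row.update({c: getattr(r, c) for c in PATTERN_COLUMNS})
        rows.append(row)
    return pd.DataFrame(rows, columns=_GENERIC_BASE_COLUMNS + NUTRIENT_COLUMNS + PATTERN_COLUMNS)


def write_generic_db(records: list[GenericFoodRecord], path: str | Path) -> None:
    write_table(generic_db_to_frame(records), path, "csv")


def _as_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).strip().lower() in {"true", "1", "yes"}


def read_specific_db(path: str | Path, source_db: str) -> list[SpecificProductRecord]:
    """Read a specific (GTIN-keyed) product database CSV.

    GTINs are normalized through the same item-number rules used by the
    enrichment cascade; records whose code fails the check digit (or is not
    a GTIN candidate at all) are kept with ``gtin_valid=False`` rather than
    silently dropped.
    """
    df = pd.read_csv(Path(path), dtype={"gtin": str}, keep_default_na=False, na_values=[""])
    if "gtin" not in df.columns:
        raise SchemaError(f"specific DB {path}: missing column gtin")
    records = []
    for rec in df.to_dict(orient="records"):
        norm = normalize_item_number(str(rec["gtin"]))
        nutrients = {
            c: float(rec[c])
            for c in NUTRIENT_COLUMNS
            if c in rec and pd.notna(rec[c])
        }
        ingredients = tuple(
            tok.strip()
            for tok in str(rec.get("ingredients") or "").split(";")
            if tok.strip()
        )
        risk = rec.get("risk_score")
        risk = None if (risk is None or pd.isna(risk) or risk == "") else str(risk)
        records.append(
            SpecificProductRecord(
                gtin=norm.gtin if norm.is_gtin else norm.digits,
                product_name=str(rec.get("product_name", "")),
                nutrients=nutrients,
                ingredients=ingredients,
                risk_score=risk,
                source_db=source_db,
                gtin_valid=norm.is_gtin,
            )
        )
    return records


def specific_db_to_frame(records: list[SpecificProductRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"gtin": r.gtin, "product_name": r.product_name}
        row.update({c: r.nutrients.get(c, float("nan")) for c in NUTRIENT_COLUMNS})
        row["ingredients"] = ";".join(r.ingredients)
        row["risk_score"] = r.risk_score or ""
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["gtin", "product_name", *NUTRIENT_COLUMNS, "ingredients", "risk_score"]
    )


def write_specific_db(records: list[SpecificProductRecord], path: str | Path) -> None:
    write_table(specific_db_to_frame(records), path, "csv")
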