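"""GTIN-13 barcode normalization and mod-10 check-digit validation.

Receipt item numbers are either genuine GTIN barcodes (8/12/13/14 digits
after stripping non-digits) or shorter supplier-internal codes.  Item
numbers with fewer than 3 or more than 14 digits are excluded outright;
everything else is either normalized to a GTIN-13 or kept as an internal
code that is eligible only for name-based matching.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

_NON_DIGIT = re.compile(r"\D+")

#: GTIN candidate lengths; all others in [3, 14] are supplier-internal codes.
_GTIN_LENGTHS = frozenset({8, 12, 13, 14})


class ItemNumberStatus(str, Enum):
    """Outcome of item-number normalization."""

    GTIN = "gtin"               # valid GTIN-13 after normalization
    INTERNAL = "internal"       # supplier-internal code, name-match only
    EXCLUDED = "excluded"       # < 3 or > 14 digits


@dataclass(frozen=True)
class NormalizedItemNumber:
    """Result of :func:`normalize_item_number` (a total function)."""

    raw: str
    digits: str
    status: ItemNumberStatus
    gtin: str | None = None

    @property
    def is_gtin(self) -> bool:
        return self.status is ItemNumberStatus.GTIN

    @property
    def is_excluded(self) -> bool:
        return self.status is ItemNumberStatus.EXCLUDED


def gtin13_check_digit(first12: str) -> int:
    """Check digit for a 12-digit GTIN body.

    Digits are weighted 1, 3, 1, ... from the left (equivalently 3, 1, 3, ...
    from the right for a 13-digit code); the check digit is the mod-10
    complement of the weighted sum.
    """
    if len(first12) != 12 or not first12.isdigit():
        raise ValueError(f"expected 12 digits, got {first12!r}")
    total = sum(int(d) * (1 if i % 2 == 0 else 3) for i, d in enumerate(first12))
    return (10 - total % 10) % 10


def is_valid_gtin13(code: str) -> bool:
    """True iff ``code`` is 13 digits with a correct mod-10 check digit."""
    if len(code) != 13 or not code.isdigit():
        return False
    return gtin13_check_digit(code[:12]) == int(code[12])


def make_gtin13(body: str | int) -> str:
    """Build a valid GTIN-13 from a 12-digit body (appending the check digit)."""
    body = str(body).zfill(12)
    return body + str(gtin13_check_digit(body))


def normalize_item_number(raw: str) -> NormalizedItemNumber:
    """Classify and normalize a raw receipt item number.

    Rules:

    * non-digits are stripped first;
    * < 3 or > 14 digits: excluded (``excluded_item_number`` territory);
    * 8 or 12 digits: zero-padded to 13 (padding preserves the check digit,
      which is positional from the right);
    * 14 digits: a leading zero is stripped to 13; a 14-digit code with a
      nonzero lead cannot be a GTIN-13 and demotes to an internal code;
    * 13 digits: taken as-is;
    * 3-7 and 9-11 digits: supplier-internal code;
    * a GTIN candidate failing the check digit demotes to an internal code
      rather than being rejected.
    """
    digits = _NON_DIGIT.sub("", str(raw))
    n = len(digits)
    if n < 3 or n > 14:
        return NormalizedItemNumber(raw=raw, digits=digits, status=ItemNumberStatus.EXCLUDED)
    if n not in _GTIN_LENGTHS:
        return NormalizedItemNumber(raw=raw, digits=digits, status=ItemNumberStatus.INTERNAL)
    if n == 14:
        if digits[0] != "0":
            return NormalizedItemNumber(raw=raw, digits=digits, status=ItemNumberStatus.INTERNAL)
        candidate = digits[1:]
    else:
        candidate = digits.zfill(13)
    if is_valid_gtin13(candidate):
        return NormalizedItemNumber(
            raw=raw, digits=digits, status=ItemNumberStatus.GTIN, gtin=candidate
        )
    return NormalizedItemNumber(raw=raw, digits=digits, status=ItemNumberStatus.INTERNAL)
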