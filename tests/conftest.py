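import pandas as pd
import pytest

from cpdtools import CohortConfig, EnrichmentConfig, enrich, generate_cohort
from cpdtools.types import PurchaseTable


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """A fast cohort preserving all structural features of the generator."""
    return CohortConfig(
        n_participants=20,
        n_retailers=10,
        n_products=300,
        months=6,
        receipts_per_month_mean=6,
        lines_per_receipt_mean=6,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_enriched(small_cohort):
    return enrich(
        small_cohort.purchases,
        small_cohort.generic_db,
        small_cohort.specific_dbs,
        EnrichmentConfig(),
    )


def make_purchases(rows: list[dict]) -> PurchaseTable:
    """Hand-built purchase table from minimal row dicts."""
    defaults = {
        "participant_id": "P1",
        "retailer_id": "R1",
        "purchase_datetime": "2022-01-10T10:00:00",
        "item_number": "5701234567899",
        "item_name": "item",
        "unit_price_ore": 1000,
        "quantity": 1,
        "discount_ore": 0,
    }
    return PurchaseTable(pd.DataFrame([{**defaults, **r} for r in rows]))
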