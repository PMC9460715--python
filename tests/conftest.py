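"""Shared fixtures: toy datasets, pools, and the published count table."""

from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")

from occubalance.balance_plan import ClassCountTable
from occubalance.dataset_io import (
    CLASS_ORDER,
    IlluminationLabel,
    SubDatasetKey,
)
from occubalance.fixtures import (
    FixtureSpec,
    generate_fixture_dataset,
    generate_fixture_pool,
)

DATA_DIR = Path(__file__).parent / "data"

# Per-class counts of a deliberately imbalanced toy cell (sums to 94).
IMBALANCED_ROW = (30, 20, 10, 5, 8, 12, 3, 6)


@pytest.fixture(scope="session")
def counts_csv_path() -> Path:
    """Published per-sub-dataset annotation counts of the public MTOA
    orchard dataset (six region/illumination slices, eight classes)."""
    return DATA_DIR / "mtoa_counts_by_illumination.csv"


@pytest.fixture(scope="session")
def mtoa_table(counts_csv_path) -> ClassCountTable:
    return ClassCountTable.read_csv(counts_csv_path)


def make_toy_spec(
    regions=("AA", "BB"), seed=7, empty_key=("BB", IlluminationLabel.LOW)
) -> FixtureSpec:
    """Imbalanced 2-region x 2-illumination toy spec; one empty slice."""
    counts = {}
    for region in regions:
        for ill in IlluminationLabel:
            key = SubDatasetKey(region, ill)
            for i, c in enumerate(CLASS_ORDER):
                empty = empty_key is not None and (region, ill) == empty_key
                counts[(key, c)] = 0 if empty else IMBALANCED_ROW[i]
    return FixtureSpec(regions=list(regions), per_cell_counts=counts, seed=seed)


@pytest.fixture(scope="session")
def toy_spec() -> FixtureSpec:
    return make_toy_spec()


@pytest.fixture(scope="session")
def toy_dataset(toy_spec):
    return generate_fixture_dataset(toy_spec)


@pytest.fixture(scope="session")
def toy_pool(toy_spec):
    return generate_fixture_pool(toy_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
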