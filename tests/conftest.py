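import numpy as np
import pandas as pd
import pytest

from morphotype import synthetic as syn
from morphotype.clustering import normalize_features

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def fixture_table() -> pd.DataFrame:
    """The default study fixture: 10 planted subtypes in 3 CGs across the
    five exposure conditions, ~10,000 cells (session-cached)."""
    return syn.default_fixture(10_000, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def fixture_normalized(fixture_table):
    return normalize_features(fixture_table)


@pytest.fixture(scope="session")
def small_mask_fields():
    """A small rasterized field set (~60 cells, mixed subtypes)."""
    cond = syn.default_conditions()[0]
    return syn.generate_population(
        syn.default_subtypes(), cond, 60, seed=11, output="masks",
        field_shape=(1200, 1200),
    )


def disc_mask(radius: int, shape=None, center=None) -> np.ndarray:
    shape = shape or (2 * radius + 5, 2 * radius + 5)
    center = center or (shape[0] // 2, shape[1] // 2)
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
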