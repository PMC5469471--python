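import numpy as np
import pytest

import meadowpack as mp
from meadowpack.matching import matches_to_pairs


@pytest.fixture(scope="session")
def small_landscape():
    """A reduced landscape: 120 meadows, 16 stock, fixed seed."""
    meadows, stock_use = mp.generate_landscape(
        n_meadows=120, n_stock=16, seed=11
    )
    return meadows, stock_use


@pytest.fixture(scope="session")
def small_pairs(small_landscape):
    meadows, stock_use = small_landscape
    eligible = mp.filter_eligible_stock(meadows, stock_use)
    matches = mp.match_meadows(eligible, meadows, stock_use)
    return matches_to_pairs(matches)


@pytest.fixture(scope="session")
def null_dataset(small_landscape, small_pairs):
    """Sampled dataset for the matched meadows, no injected effects."""
    meadows, stock_use = small_landscape
    sampled = sorted(
        {p.stock_meadow_id for p in small_pairs}
        | {p.control_meadow_id for p in small_pairs}
    )
    return mp.generate_dataset(
        sampled, meadows, stock_use, effect_config=mp.EffectConfig(), seed=11
    )


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def cheap_niches():
    """A tiny species pool for tests where composition is incidental."""
    return [
        mp.SpeciesNiche("wet_sedge", 1.5, 1.0, 30.0, 1.0),
        mp.SpeciesNiche("dry_sedge", -1.5, 1.0, 30.0, 1.0),
    ]
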