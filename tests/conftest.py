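from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from aqualeaf import GeneratorConfig, SpectraSet, generate_experiment

RECOVERY_SEEDS = (0, 1, 2, 3, 4)


@pytest.fixture(scope="session")
def default_experiments():
    """Full-size synthetic experiments for the recovery seeds, generated once."""
    return {
        seed: generate_experiment(replace(GeneratorConfig(), seed=seed))
        for seed in RECOVERY_SEEDS
    }


@pytest.fixture(scope="session")
def small_experiment():
    """Reduced design (2 plants per arm) for fast unit tests."""
    cfg = replace(GeneratorConfig(), n_plants_per_arm=2, seed=7)
    return generate_experiment(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_set(rng):
    """Hand-sized SpectraSet with full metadata (6 spectra, 30 bands)."""
    wl = np.linspace(1000.0, 1290.0, 30)
    absorb = 0.5 + 0.1 * rng.standard_normal((6, 30))
    meta = pd.DataFrame(
        {
            "spectrum_id": [f"s{i}" for i in range(6)],
            "line_label": ["tolerant"] * 3 + ["sensitive"] * 3,
            "plant_id": ["p1", "p1", "p2", "p3", "p3", "p4"],
            "leaf_index": [2, 3, 4, 2, 3, 4],
            "replicate": [1, 2, 3, 1, 2, 3],
            "treatment": ["control", "stress", "stress"] * 2,
            "day": [3, 3, 7, 3, 7, 17],
            "stage_tag": ["drought"] * 6,
        }
    )
    return SpectraSet(wl, absorb, meta)
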