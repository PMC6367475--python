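import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mirarray.config import SimConfig
from mirarray.simulate import simulate_all


@pytest.fixture(scope="session")
def small_sim():
    """A small planted fixture shared by recovery tests (seeded, deterministic)."""
    cfg = SimConfig(rng_seed=42, n_contigs=50, n_mirnas=40, site_plant_prob=1.0,
                    n_de_per_comparison=8)
    mirnas, contigs, design, matrix, truth = simulate_all(cfg)
    return {"config": cfg, "mirnas": mirnas, "contigs": contigs,
            "design": design, "matrix": matrix, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
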