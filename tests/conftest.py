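"""Shared fixtures for the deersem test suite."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from deersem.raster import Raster
from deersem.synthgen import SimConfig, generate_world

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def lmm_oracle_data() -> pd.DataFrame:
    """Fixed dataset with externally computed mixed-model reference fits."""
    return pd.read_csv(DATA_DIR / "lmm_oracle.csv")


@pytest.fixture(scope="session")
def small_world():
    """One full synthetic world, shared across tests (read-only)."""
    cfg = SimConfig(rng_seed=7)
    land, transects, obs, culls = generate_world(cfg)
    return {"config": cfg, "landscape": land, "transects": transects,
            "observations": obs, "culls": culls}


@pytest.fixture()
def flat_raster() -> Raster:
    return Raster(np.full((40, 50), 3.0), cellsize=100.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
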