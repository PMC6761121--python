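import numpy as np
import pandas as pd
import pytest

from pestmap import GridSpec, PipelineConfig, RegionMask, WorldConfig, generate_world, run_pipeline


@pytest.fixture(scope="session")
def exact_world():
    """Zero-noise world with single-covariate linear truth: the exact
    fixed point of the whole pipeline."""
    cfg = WorldConfig(
        noise_sd_frac=0.0,
        highlow_spread_frac=0.0,
        missing_rate=0.0,
        faostat_perturb_frac=0.0,
        covariates_per_response=(1, 1),
        seed=1,
    )
    return generate_world(cfg)


@pytest.fixture(scope="session")
def exact_result(exact_world):
    return run_pipeline(exact_world, PipelineConfig(top_k_covariates=1))


@pytest.fixture(scope="session")
def noisy_world():
    cfg = WorldConfig(
        grid_rows=48,
        grid_cols=96,
        noise_sd_frac=0.05,
        highlow_spread_frac=0.2,
        missing_rate=0.05,
        faostat_perturb_frac=0.05,
        seed=11,
    )
    return generate_world(cfg)


@pytest.fixture(scope="session")
def noisy_result(noisy_world):
    return run_pipeline(noisy_world, PipelineConfig())


@pytest.fixture
def small_spec():
    return GridSpec(n_rows=6, n_cols=8, lon_min=0, lon_max=8, lat_min=0, lat_max=6)


@pytest.fixture
def two_region_mask(small_spec):
    labels = np.zeros(small_spec.shape, dtype=int)
    labels[:, 4:] = 1
    return RegionMask(labels=labels, adjacency={0: {1}, 1: {0}})


def make_panel(rows):
    """rows: (ai, crop, state, year, high, low)."""
    return pd.DataFrame(
        rows, columns=["ai", "crop", "state", "year", "mass_high", "mass_low"]
    )
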