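from pathlib import Path

import numpy as np
import pytest

from lcluc import ScenarioConfig, Transition, default_legend, generate_series, rect_mask

EXAMPLES = Path(__file__).resolve().parents[1] / "examples"


@pytest.fixture(scope="session")
def legend():
    return default_legend()


@pytest.fixture
def demo_config_path():
    return EXAMPLES / "demo.toml"


def make_scenario(
    grid=(100, 100),
    transitions=(),
    regions=None,
    region_initial=None,
    background=None,
    noise_rate=0.0,
    seed=0,
    **kwargs,
):
    """Small scenario factory with a full-grid default region."""
    regions = regions if regions is not None else {"all": rect_mask(grid, 0, grid[0], 0, grid[1])}
    return ScenarioConfig(
        grid_shape=grid,
        regions=regions,
        region_initial=region_initial or {},
        background=background or {"GRAS": 0.6, "AGRI": 0.4},
        transitions=list(transitions),
        noise_rate=noise_rate,
        seed=seed,
        **kwargs,
    )


@pytest.fixture
def gras_to_agri_series():
    """Noise-free 13-year series converting grassland to cropland at 1%/yr."""
    cfg = make_scenario(
        transitions=[Transition("all", "GRAS", "AGRI", 0.01, "random")], seed=3
    )
    return generate_series(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
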