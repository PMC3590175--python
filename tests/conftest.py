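import dataclasses

import numpy as np
import pytest

from restalff.preprocess import PreprocessParams
from restalff.simulate import ConnectivityEffect, EffectRoi, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """A small, fast cohort: 16x16x12 grid, 3 + 6 subjects (the larger
    patient group keeps the 3-covariate partial correlation estimable),
    with an amplitude ROI and a connectivity pair inside the smaller mask."""
    return SimulationConfig(
        grid_dims=(16, 16, 12),
        n_per_group=(3, 6),
        effect_rois=(EffectRoi(center_mm=(6.0, 6.0, 0.0), radius_mm=6.0, amplitude_ratio=1.5),),
        connectivity_effects=(
            ConnectivityEffect(
                seed_center_mm=(6.0, 6.0, 0.0),
                target_center_mm=(-9.0, -6.0, 0.0),
                radius_mm=6.0,
                weight_a=0.8,
                weight_b=0.2,
            ),
        ),
        seed=7,
    )


@pytest.fixture
def default_pre():
    return PreprocessParams()


@pytest.fixture
def amplitude_only_config(small_config):
    return dataclasses.replace(small_config, connectivity_effects=())
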