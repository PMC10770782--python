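import pytest

from cawarn.config import PipelineConfig
from cawarn.model import ModelConfig
from cawarn.pipeline import preprocess_cohort
from cawarn.preprocess import RegularGrid
from cawarn.simulate import SimConfig, generate_cohort

FAST_MODEL = ModelConfig(n_trees_max=30, early_stopping_rounds=30)


@pytest.fixture(scope="session")
def small_cohort():
    """60 stays, strong destabilization, high prevalence: quick but learnable."""
    cfg = SimConfig(n_stays=60, ca_fraction=0.3, effect_size=2.0, onset_hours_before_end=6, seed=5)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_grids(small_cohort):
    grids, labels = preprocess_cohort(small_cohort.records, small_cohort.labels, PipelineConfig())
    return grids, labels


def random_grid(rng, T=24, C=9):
    from cawarn.channels import GRID_CHANNELS

    channels = list(GRID_CHANNELS) if C == 9 else [f"CH{i}" for i in range(C)]
    return RegularGrid(stay_id="R", values=rng.standard_normal((T, C)), channels=channels)
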