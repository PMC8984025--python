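import numpy as np
import pytest

from paddy.config import FieldConfig
from paddy.indices import build_feature_stack
from paddy.prep import partition_folds, select_tiles, tile
from paddy.simulate import simulate_field


@pytest.fixture(scope="session")
def small_field():
    """A 120x120 booting-stage field: small but spatially structured."""
    cfg = FieldConfig(
        height_px=120,
        width_px=120,
        n_dates=1,
        stage_labels=("booting",),
        buffer_cells=5,
        seed=11,
    )
    stacks, yield_raster, latent = simulate_field(cfg)
    return cfg, stacks[0], yield_raster, latent


@pytest.fixture(scope="session")
def small_tiles(small_field):
    _, stack, yield_raster, _ = small_field
    return tile(build_feature_stack(stack), yield_raster)


@pytest.fixture(scope="session")
def small_split(small_tiles):
    """(train, validation, test) tiles of fold B on the small field."""
    fold = {f.fold_id: f for f in partition_folds(small_tiles)}["B"]
    return tuple(
        select_tiles(small_tiles, fold, role)
        for role in ("train", "validation", "test")
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
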