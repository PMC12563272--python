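import numpy as np
import pytest
from hypothesis import settings

import wellquant as wq

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


#: Small flat well used throughout the suite: fast to render yet large
#: enough to hold ~100 non-overlapping 15 µm cells at the default scale.
SMALL_FLAT = wq.WellSpec(
    shape="flat",
    top_radius_um=120.0,
    bottom_diameter_um=240.0,
    pixel_scale_um_per_px=1.6,
)

SMALL_U = wq.WellSpec(
    shape="u_bottom",
    top_radius_um=120.0,
    depth_um=40.0,
    pixel_scale_um_per_px=1.6,
)


@pytest.fixture(scope="session")
def small_flat():
    return SMALL_FLAT


@pytest.fixture(scope="session")
def small_u():
    return SMALL_U


@pytest.fixture(scope="session")
def fixture_50(small_flat):
    """Seed-7 frame with 50 cells and no bubbles, plus its ground truth."""
    return wq.render_well(small_flat, wq.CellRenderSpec(), 50, seed=7)


@pytest.fixture(scope="session")
def trained_model(small_flat):
    """Segmenter trained on 40 synthetic frames (bubbles included) with the
    10-frame validation set and the shared true ROI."""
    initial, _, _, validation, roi = wq.benchmark_dataset(
        small_flat,
        n_initial=40,
        n_pool=0,
        n_validation=10,
        mean_cells=40,
        seed=11,
        bubble_probability=0.5,
    )
    model = wq.train_segmenter(initial, seed=3)
    return model, validation, roi


def mask_of(truth):
    return wq.SegMask(truth.mask)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
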