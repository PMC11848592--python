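import numpy as np
import pytest

from msiseg import MSIDataset, PhantomSpec, TrainConfig, generate_phantom, tic_normalize


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dataset(rng, n_rows=5, n_cols=6, n_ions=8, mask=None):
    """A small random MSIDataset, optionally with an irregular tissue mask."""
    if mask is None:
        mask_arr = np.ones((n_rows, n_cols), dtype=bool)
    else:
        mask_arr = np.asarray(mask, dtype=bool)
    rr, cc = np.nonzero(mask_arr)
    order = np.argsort(rr * n_cols + cc)
    pixel_index = np.stack([rr[order], cc[order]], axis=1)
    intensities = rng.gamma(2.0, 1.0, size=(len(pixel_index), n_ions))
    mz = 100.0 + 5.0 * np.arange(n_ions)
    return MSIDataset(
        intensities, mz, (n_rows, n_cols), pixel_index,
        tissue_mask=None if mask is None else mask_arr,
    )


@pytest.fixture
def small_phantom():
    """A quick well-separated phantom for training-behavior tests."""
    spec = PhantomSpec(grid_shape=(16, 16), n_regions=3, n_ions=30,
                       enriched_per_region=4, seed=7)
    ds, truth = generate_phantom(spec)
    return tic_normalize(ds), truth, spec


@pytest.fixture
def fast_config():
    """Reduced-schedule config for tests that only need training mechanics."""
    return TrainConfig(warmup_epochs=100, fc_epochs=200, seed=7, hidden_dim=64,
                       n_neighbors=10)
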