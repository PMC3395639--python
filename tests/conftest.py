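import numpy as np
import pytest

from epinet.datasets import DEFAULT_LABEL_CODES, BoldDataset
from epinet.synthetic import BoldSimConfig, generate_bold


@pytest.fixture
def small_bold():
    """Small noisy dataset exercising every tissue class, fast to process."""
    cfg = BoldSimConfig(
        n_voxels_per_hemisphere=20,
        n_frames=300,
        roi_fraction=0.4,
        inter_corr=0.5,
        intra_corr=0.6,
        noise_sd=1.0,
        seed=7,
    )
    return generate_bold(cfg)


@pytest.fixture
def exact_bold():
    """Noise-free dataset whose sample correlations equal the planted ones."""
    cfg = BoldSimConfig(
        n_voxels_per_hemisphere=10,
        n_frames=600,
        roi_fraction=0.5,
        inter_corr=0.6,
        intra_corr=0.7,
        noise_sd=0.0,
        seed=3,
    )
    return generate_bold(cfg)


def make_bold_from_series(series: np.ndarray, labels_flat: np.ndarray,
                          tr: float = 0.5,
                          voxel_size=(0.5, 0.5, 1.5)) -> BoldDataset:
    """Hand-built dataset: one voxel per entry of `labels_flat` on a line."""
    v, t = series.shape
    data = series.reshape(v, 1, 1, t)
    labels = np.asarray(labels_flat, dtype=np.int16).reshape(v, 1, 1)
    mask = labels > 0
    return BoldDataset(data=data, tr=tr, brain_mask=mask, labels=labels,
                       voxel_size=voxel_size)


CODES = DEFAULT_LABEL_CODES
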