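import numpy as np
import pytest

from cnvsnn.core import Segment
from cnvsnn.layout import standard_1020_layout
from cnvsnn.synthio import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def layout():
    return standard_1020_layout()


@pytest.fixture(scope="session")
def small_dataset():
    """Ten fast trials at a reduced sampling rate for unit tests."""
    cfg = SyntheticConfig(
        n_trials=10, fs=32, cnv_amplitude=-10.0, noise_sd=5.0, artifact_rate=0.0, seed=11
    )
    return cfg, generate_dataset(cfg)


def make_segment(data, label=0, trial_id=0, labels=None):
    data = np.asarray(data, dtype=float)
    if labels is None:
        labels = tuple(f"ch{i:02d}" for i in range(data.shape[0]))
    return Segment(
        data=data,
        label=label,
        trial_id=trial_id,
        marker_pair=("5", "4"),
        original_length=data.shape[1],
        channel_labels=labels,
    )
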