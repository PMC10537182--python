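import numpy as np
import pandas as pd
import pytest

from eegstates.feature_bank import FeatureMatrix
from eegstates.synthetic import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_segments():
    """3-channel, 1-minute-per-state synthetic set: 2 segments per class."""
    cfg = SimConfig(channels=3, minutes_per_state=1.0, master_seed=7)
    return generate_dataset(cfg)


def make_blob_matrix(
    n_per_class: int = 30,
    n_features: int = 10,
    separation: float = 2.0,
    n_classes: int = 3,
    n_channels: int = 1,
    seed: int = 0,
    transform: str = "mdwt",
) -> FeatureMatrix:
    """Gaussian-blob FeatureMatrix with class means ``separation`` apart."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for k in range(n_classes):
        centre = rng.standard_normal(n_features * n_channels) * 0.3 + k * separation
        rows.append(centre + rng.standard_normal((n_per_class, n_features * n_channels)))
        labels += [f"class{k}"] * n_per_class
    meta = pd.DataFrame(
        {
            "transform": transform,
            "subband": 1,
            "channel": np.repeat(np.arange(n_channels), n_features),
            "feature": [f"f{j}" for j in range(n_features)] * n_channels,
        }
    )
    return FeatureMatrix(np.vstack(rows), np.array(labels), meta)
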