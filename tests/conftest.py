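import numpy as np
import pandas as pd
import pytest

from guildspace import synthetic_data as synth


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_measurements():
    """One fully measured toy jaw (all lengths in mm)."""
    return pd.DataFrame([{
        "taxon_id": "toy",
        "jaw_length": 120.0,
        "tooth_row_length": 66.0,
        "max_depth": 30.0,
        "symphysis_length": 24.0,
        "symphysis_angle": 32.0,
        "inlever_closing": 25.0,
        "inlever_opening": 20.0,
        "outlever_anterior": 100.0,
        "outlever_posterior": 50.0,
        "articulation_offset_raw": 9.0,
    }])


@pytest.fixture
def small_guild_data():
    """Well-separated 3-guild character data at modest size."""
    cfg = synth.SyntheticConfig(n_taxa=45, n_guilds=3, n_clades=6,
                                separation=8.0, seed=11)
    return synth.generate_functional_table(cfg)


def blobs(rng, centers, n_per, sd=1.0):
    """Gaussian blobs with known labels, as (DataFrame, labels)."""
    centers = np.asarray(centers, dtype=float)
    pts, labels = [], []
    for i, c in enumerate(centers):
        pts.append(rng.normal(loc=c, scale=sd, size=(n_per, len(c))))
        labels.extend([i + 1] * n_per)
    x = np.vstack(pts)
    idx = [f"t{i:03d}" for i in range(len(x))]
    return pd.DataFrame(x, index=idx), pd.Series(labels, index=idx)
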