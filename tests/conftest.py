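import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from megfc.connectivity import FCMatrix, ThresholdedNetwork
from megfc.preprocess import BandSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_network(
    adjacency: np.ndarray,
    R: np.ndarray | None = None,
    labels: list[str] | None = None,
    region_of: dict[str, str] | None = None,
    K: int = 100,
) -> tuple[ThresholdedNetwork, FCMatrix]:
    """Build a ThresholdedNetwork (+ matching FCMatrix) directly from an
    adjacency matrix, bypassing the thresholding pipeline."""
    adjacency = np.asarray(adjacency, dtype=bool)
    n = adjacency.shape[0]
    if R is None:
        R = adjacency.astype(float) * 0.5
        np.fill_diagonal(R, 1.0)
    labels = labels or [f"ch{i}" for i in range(n)]
    region_of = region_of or {c: "frontal" for c in labels}
    band = BandSpec("gamma", 30, 80)
    fc = FCMatrix(R=R, K=K, band=band, period="ictal",
                  channel_labels=labels, region_of=region_of)
    net = ThresholdedNetwork(
        adjacency=adjacency,
        excitatory=R > 0,
        r_threshold=0.1,
        alpha=0.05,
        K=K,
        k_used=K,
        band=band,
        period="ictal",
        channel_labels=labels,
        region_of=region_of,
    )
    return net, fc
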