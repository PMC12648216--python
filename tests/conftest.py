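import numpy as np
import pytest

from raic.hmm import build_emissions
from raic.synthetic import SyntheticConfig
from raic.types import ROI, ExpertGazePattern


@pytest.fixture
def cfg_small() -> SyntheticConfig:
    return SyntheticConfig(seed=11, n_participants=8)


@pytest.fixture
def egp5() -> ExpertGazePattern:
    """Five well-separated elliptical ROIs on the standard canvas."""
    rois = [
        ROI(i + 1, 250 + i * 350, 300 + (i % 2) * 400, 200, 140, 0.0)
        for i in range(5)
    ]
    return ExpertGazePattern("fix5", rois)


@pytest.fixture
def emissions5(egp5):
    return build_emissions(egp5)


def make_chain(n: int, self_p: float) -> np.ndarray:
    """Ergodic chain with given self-transition and uniform off-diagonal."""
    A = np.full((n, n), (1 - self_p) / (n - 1))
    np.fill_diagonal(A, self_p)
    return A
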