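import numpy as np
import pytest

# Pooled cross-validation confusion counts of the reference single-channel
# study (rows = expert stage, cols = algorithm stage, N1 N2 N3 R W order).
# Used as a worked example throughout the evaluation tests.
TABLE5_COUNTS = np.array(
    [
        [1654, 262, 8, 366, 472],
        [1270, 13696, 1231, 760, 621],
        [7, 469, 4966, 6, 143],
        [899, 340, 0, 6164, 308],
        [441, 34, 23, 138, 2744],
    ],
    dtype=int,
)


@pytest.fixture
def table5_counts() -> np.ndarray:
    return TABLE5_COUNTS.copy()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_labelled_data():
    """Five well-separated Gaussian clusters in [0,1]^10, one per stage."""
    from wavesleep import STAGES

    gen = np.random.default_rng(7)
    centers = gen.uniform(0.15, 0.85, size=(5, 10))
    X, y = [], []
    for i, stage in enumerate(STAGES):
        X.append(centers[i] + 0.02 * gen.standard_normal((30, 10)))
        y.extend([stage] * 30)
    return np.clip(np.vstack(X), 0, 1), np.array(y)
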