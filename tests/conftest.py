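import numpy as np
import pandas as pd
import pytest

from hopland import HopfieldLandscape, StageAnnotation, generate_arc_dataset


@pytest.fixture(scope="session")
def arc_default():
    """Default synthetic arc time course (matrix, annotation, ground truth)."""
    return generate_arc_dataset()


@pytest.fixture(scope="session")
def fitted_default(arc_default):
    matrix, annotation, _ = arc_default
    return HopfieldLandscape(matrix, annotation).fit()


@pytest.fixture
def toy_matrix():
    """3 genes x 4 samples with distinct variances."""
    return pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [10.0, 10.5, 9.5, 10.0],
         [0.0, -5.0, 5.0, 0.0]],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2", "s3", "s4"])


@pytest.fixture
def toy_annotation():
    return StageAnnotation(
        {"s1": "early", "s2": "early", "s3": "late", "s4": "late"},
        ["early", "late"])


def brute_force_energy(state, weights):
    """Independent double-loop oracle for -1/2 sum_i sum_j H_i w_ij H_j."""
    h = np.asarray(state, dtype=float)
    w = np.asarray(weights, dtype=float)
    total = 0.0
    for i in range(h.size):
        for j in range(h.size):
            total += h[i] * w[i, j] * h[j]
    return -0.5 * total


def random_instance(rng, n):
    """Random ternary state + random symmetric zero-diagonal weights."""
    h = rng.integers(-1, 2, size=n)
    raw = rng.uniform(-1.0, 1.0, size=(n, n))
    w = (raw + raw.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return h, w
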