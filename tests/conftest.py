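import numpy as np
import pytest

from nanoloc.locproc import make_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    """Nine localizations across three frames with sigma and intensity."""
    return make_table(
        frame=[0, 0, 0, 1, 1, 1, 2, 2, 2],
        x=[100.0, 500.0, 900.0, 110.0, 505.0, 910.0, 95.0, 498.0, 905.0],
        y=[100.0, 100.0, 100.0, 108.0, 95.0, 102.0, 103.0, 99.0, 98.0],
        sigma=[150.0, 180.0, 120.0, 160.0, 140.0, 130.0, 155.0, 145.0, 150.0],
        intensity=[1000.0] * 9,
    )


@pytest.fixture
def clustered_pair():
    """Two clearly clustered channels (B = noisy copy of A) for coloc tests."""
    gen = np.random.default_rng(777)
    centers = np.array([[2000.0, 2000.0], [7000.0, 3000.0], [4000.0, 7500.0]])
    pts = []
    for c in centers:
        pts.append(gen.normal(c, 120.0, size=(400, 2)))
    pts.append(gen.uniform(0, 10000, size=(400, 2)))
    pts = np.concatenate(pts)
    frames = gen.integers(0, 1000, len(pts))
    a = make_table(frames, pts[:, 0], pts[:, 1])
    noisy = pts + gen.normal(0, 15.0, pts.shape)
    b = make_table(frames, noisy[:, 0], noisy[:, 1])
    return a, b
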