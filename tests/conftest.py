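import numpy as np
import pytest

from pspgleason.synthetic import SyntheticCoreSpec, generate_core

OVERFIT_LAYOUTS = [
    [(0, 1.0)],
    [(3, 0.7), (0, 0.3)],
    [(4, 0.7), (0, 0.3)],
    [(5, 0.7), (0, 0.3)],
    [(3, 0.5), (4, 0.5)],
    [(4, 0.5), (5, 0.5)],
    [(3, 0.4), (5, 0.4), (0, 0.2)],
    [(0, 0.25), (3, 0.25), (4, 0.25), (5, 0.25)],
]


def make_cores(n=8, size=96, seed=0):
    """n synthetic cores spanning benign-only through mixed-grade layouts."""
    cores = []
    for i in range(n):
        layout = OVERFIT_LAYOUTS[i % len(OVERFIT_LAYOUTS)]
        rgb, truth = generate_core(
            SyntheticCoreSpec(image_size=size, region_layout=layout, seed=seed * 1000 + i))
        cores.append((rgb.astype(np.float64) / 255.0, truth))
    return cores


@pytest.fixture(scope="session")
def small_cores():
    """Four 64-px cores for cheap smoke tests."""
    return make_cores(n=4, size=64, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
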