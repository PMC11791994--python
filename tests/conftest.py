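import numpy as np
import pytest

from rootgrain import ScaleModel, gen_scene


@pytest.fixture(scope="session")
def small_scene():
    """One reusable 12-root scene at desk scale (300 dpi)."""
    return gen_scene(n_roots=12, pattern_mix=0.5, seed=42, scale=ScaleModel(300),
                     canvas_mm=45.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def random_blob_mask(rng, shape=(40, 40), p=0.35):
    """Random speckle mask; usually several components."""
    return rng.random(shape) < p
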