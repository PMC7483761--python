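import numpy as np
import pytest

from cycleseg import groundtruth as gt
from cycleseg import synthetic_data as sd


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic synthetic volume plus its annotations."""
    cfg = sd.SimulationConfig(shape=(16, 48, 48), n_nuclei=3, min_separation=8.0, seed=11)
    vol, table = sd.simulate_volume(cfg)
    return cfg, vol, table


#: Target rendering used by the learning tests: spheres of radius
#: sigma * sqrt(2 ln(1/tau)) ~ 5.4 voxels, covering the nucleus's full
#: visible extent (blobs are clipped at 3 sigma and fade into the noise
#: floor near 2.4 sigma), so labels match what the images actually show.
TARGET_SPEC = gt.GaussianTargetSpec(sigma=2.5, threshold=0.1)


def render_target(table, shape, spec=TARGET_SPEC):
    return gt.binarize_target(gt.gaussian_target(table, shape, spec), spec.threshold).data


@pytest.fixture(scope="session")
def synthetic_training_set():
    """Training corpus for the learning tests.

    Twenty 96x96x24 volumes with 3-8 nuclei each as (volume, annotations,
    binary target) triples, plus four held-out test triples.
    """
    rng = np.random.default_rng(42)
    train = []
    for i in range(20):
        cfg = sd.SimulationConfig(shape=(24, 96, 96), n_nuclei=int(rng.integers(3, 9)), seed=1000 + i)
        vol, tab = sd.simulate_volume(cfg)
        train.append((vol, tab, render_target(tab, vol.shape)))
    test = []
    for i in range(4):
        cfg = sd.SimulationConfig(shape=(24, 96, 96), n_nuclei=int(rng.integers(3, 9)), seed=2000 + i)
        vol, tab = sd.simulate_volume(cfg)
        test.append((vol, tab, render_target(tab, vol.shape)))
    return train, test
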