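from dataclasses import replace

import numpy as np
import pytest

import raccmap as rm

# Study conditions for the noisy-phantom checks: additive Gaussian noise at
# ~3% of the 8-bit range, background thresholds at ~3 sigma of the noise.
NOISE_SD = 8.0
NOISY_THRESHOLD = 25.0
NOISY_SEED = 7


@pytest.fixture(scope="session")
def presets():
    return rm.preset_scenes()


@pytest.fixture(scope="session")
def cylinders_pair(presets):
    return rm.build_scene(presets["overlapping_cylinders"])


@pytest.fixture(scope="session")
def spheres_pair(presets):
    return rm.build_scene(presets["partial_spheres"])


@pytest.fixture(scope="session")
def noisy_spheres_pair(presets):
    scene = replace(presets["partial_spheres"], noise_sd=NOISE_SD, seed=NOISY_SEED)
    return rm.build_scene(scene)


@pytest.fixture(scope="session")
def noisy_thresholds():
    return rm.ColocThresholds(NOISY_THRESHOLD, NOISY_THRESHOLD)


@pytest.fixture(scope="session")
def noisy_spheres_run(noisy_spheres_pair, noisy_thresholds):
    """Full pipeline on the noisy partial-spheres phantom (theta=45)."""
    score, model = rm.score_volume(noisy_spheres_pair, noisy_thresholds)
    return noisy_spheres_pair, noisy_thresholds, score, model


def random_pairs(rng, n=50, spread=60.0):
    """Random joint-intensity samples with a positive linear trend."""
    x = rng.uniform(0, 255, size=n)
    y = 0.8 * x + 20 + rng.normal(0, spread, size=n)
    return x, np.clip(y, 0, 255)


def stats_from_xy(x, y):
    pair = rm.ChannelPair(
        np.asarray(x, dtype=float).reshape(1, 1, -1),
        np.asarray(y, dtype=float).reshape(1, 1, -1),
        i_max=255.0,
    )
    mask = np.ones(pair.shape, dtype=bool)
    return rm.sample_stats(pair, mask)
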