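import numpy as np
import pytest

from calltag.scene import SceneConfig, WhaleSpec, simulate_scene


def make_scene(n_whales=2, duration_s=600.0, noise_sd=0.0, seed=11, **kw):
    whales = [
        WhaleSpec("mother", "adult", "F", "mother"),
        WhaleSpec("calf", "calf", "F", "calf"),
        WhaleSpec("escort", "adult", "M", "escort/adult"),
    ][:n_whales]
    d = 50.0 * (1.0 - np.eye(n_whales))
    cfg = SceneConfig(
        whales=whales,
        duration_s=duration_s,
        pairwise_distance_m=d,
        noise_rl_sd_db=noise_sd,
        seed=seed,
        **kw,
    )
    return simulate_scene(cfg)


@pytest.fixture(scope="session")
def noiseless_scene():
    """Three tagged whales, 600 s, no level jitter: ideal assignment setting."""
    return make_scene(n_whales=3)


@pytest.fixture(scope="session")
def pair_scene():
    """Mother-calf pair, short record, no jitter."""
    return make_scene(n_whales=2, duration_s=300.0, seed=21)
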