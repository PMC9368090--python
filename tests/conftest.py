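import numpy as np
import pytest

from coronalstack import SynthParams, generate_brain


@pytest.fixture(scope="session")
def small_brain():
    """A modest jittered brain with all four channels (8 um/px)."""
    params = SynthParams(n_slices=6, microns_per_pixel=8.0, rng_seed=7)
    stacks, gt = generate_brain(params)
    return params, stacks, gt


@pytest.fixture(scope="session")
def noiseless_brain():
    """Jitter- and noise-free brain for exact geometric checks (8 um/px)."""
    params = SynthParams(
        n_slices=11,
        microns_per_pixel=8.0,
        area_noise_sd_mm2=0.0,
        rotation_jitter_deg=0.0,
        translation_jitter_um=0.0,
        rng_seed=11,
    )
    stacks, gt = generate_brain(params, channels=("DAPI", "Iba1", "IgG"))
    return params, stacks, gt


@pytest.fixture(scope="session")
def pnn_brain():
    """Finely sampled lesioned brain for WFA+ cell detection (4 um/px)."""
    params = SynthParams(
        n_slices=4,
        microns_per_pixel=4.0,
        anchor_bregma_mm=1.54,
        area_start_mm2=19.0,
        area_end_mm2=24.0,
        rotation_jitter_deg=0.0,
        translation_jitter_um=0.0,
        rng_seed=21,
    )
    stacks, gt = generate_brain(params, channels=("DAPI", "Iba1", "WFA"))
    return params, stacks, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
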