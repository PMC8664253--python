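import numpy as np
import pytest

from cryoblur import synthetic as syn


@pytest.fixture(scope="session")
def cryo_scene():
    """One noisy lifea2-cryo acquisition with ground truth (shared, seed 0)."""
    spec = syn.lifea2_cryo(seed=0)
    stack, truth = syn.generate_tcspc_stack(spec)
    return stack, truth


@pytest.fixture(scope="session")
def mono_stack():
    """Noise-free monoexponential stack (inactive state only, no background,
    no drift, delta IRF) for machine-precision phasor checks."""
    spec = syn.SceneSpec(
        shape=(16, 16),
        n_frames=1,
        background_rate=0.0,
        drift_per_frame=(0.0, 0.0),
        donor_only_fraction=0.0,
        blobs=(syn.Blob(center=(8.0, 8.0), radius=6.0, alpha=0.0,
                        photons_per_pixel=1000.0),),
    )
    stack, truth = syn.generate_tcspc_stack(spec, noise_free=True)
    return stack, truth, spec


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
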