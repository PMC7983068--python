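import numpy as np
import pytest

import darcyflow as df

# reference study conditions: 60^3 voxels at 1 mm, 30 frames at 2 s,
# eight constant-speed blocks spanning 0.5-4 mm/s (package defaults)
REF_SEED = 12345


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless reference phantom with ground truth."""
    cfg = df.PhantomConfig(noise_sigma=0.0, seed=REF_SEED)
    img, gt = df.build_phantom(cfg)
    return cfg, img, gt


@pytest.fixture(scope="session")
def noisy_phantom():
    """Reference phantom at sigma/amplitude = 0.02."""
    cfg = df.PhantomConfig(seed=REF_SEED)
    cfg.noise_sigma = 0.02 * cfg.contrast_scale * cfg.porosity
    img, gt = df.build_phantom(cfg)
    return cfg, img, gt


@pytest.fixture(scope="session")
def clean_saturation(clean_phantom):
    """Saturation-normalized series + AIF from the noiseless phantom."""
    cfg, img, gt = clean_phantom
    base = df.compute_baseline(img, 2)
    enh = df.enhancement(img, base)
    aif = df.extract_aif(enh, gt.labels)
    sat = df.normalize_to_saturation(enh, aif)
    return sat, aif, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(REF_SEED)


def gamma_curve(t, t0=4.0, alpha=2.0, beta=3.0, amplitude=1.0):
    """Plain-python gamma-variate used as an independent reference shape."""
    t = np.asarray(t, dtype=float)
    dt = t - t0
    return np.where(dt > 0, amplitude * (dt / (alpha * beta)) ** alpha
                    * np.exp(alpha - dt / beta), 0.0)
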