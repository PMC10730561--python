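import numpy as np
import pytest
from dataclasses import replace

import aadkit as ak
from aadkit.synthetic import default_forward_model


@pytest.fixture(scope="session")
def cfg():
    return ak.ExperimentConfig(seed=7)


@pytest.fixture(scope="session")
def noisefree_dataset(cfg):
    """Full-design noise-free dataset: 30 one-minute trials, 4:1 gain ratio."""
    model = default_forward_model(cfg, cfg.seed, noise_sd=0.0)
    return ak.generate_dataset(cfg, cfg.seed, model=model)


@pytest.fixture(scope="session")
def noisefree_run(cfg, noisefree_dataset):
    """Offline + real-time evaluation of the noise-free dataset."""
    return ak.run_all(cfg, noisefree_dataset)


def small_dataset(seed=0, noise_sd=0.0, n_fixed=4, n_switching=1,
                  duration_s=20.0, **model_kw):
    """Reduced-scale dataset for fast unit tests (20-s trials, 6 windows)."""
    cfg = ak.ExperimentConfig(seed=seed)
    model = default_forward_model(cfg, seed, noise_sd=noise_sd, **model_kw)
    ds = ak.generate_dataset(cfg, seed, model=model, n_fixed=n_fixed,
                             n_switching=n_switching, duration_s=duration_s)
    return cfg, ds


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
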