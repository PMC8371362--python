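import numpy as np
import pytest

from eegpf.network import ModelConfig, init_params
from eegpf.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_model_config():
    return ModelConfig(n_bands=3, n_channels=4, n_segments=3, d_embed=5,
                       d_attn=4, u_spatial=4, k_compress=3, v_temporal=5, seed=0)


@pytest.fixture(scope="session")
def tiny_params(tiny_model_config):
    return init_params(tiny_model_config)


@pytest.fixture(scope="session")
def small_dataset():
    """15 subjects, 3 well-separated clusters, short trials."""
    cfg = GeneratorConfig(n_clusters=3, subjects_per_cluster=5, n_trials=4,
                          n_channels=8, fs=32.0, trial_length_s=18.0,
                          cluster_sep=10.0, signal_snr=1.2, seed=7)
    return generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
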