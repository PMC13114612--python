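import numpy as np
import pytest

from dfcmamba import DFCConfig, ModelConfig, build_dfc
from dfcmamba.model import DFCClassifier
from dfcmamba.ssm import MambaConfig
from dfcmamba.vae import VAEArchitecture


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_model_cfg():
    """A very small full pipeline for fast structural tests."""
    return ModelConfig(
        vae=VAEArchitecture(encoder_dims=[12, 8], latent_dim=6, kl_weight=1.0),
        mamba=MambaConfig(d_model=6, d_state=3, d_conv=2, expand=2, n_layers=2,
                          dropout_p=0.15),
        kan_hidden=4,
        n_classes=2,
    )


@pytest.fixture
def tiny_model(tiny_model_cfg):
    return DFCClassifier(tiny_model_cfg, np.random.default_rng(7))


@pytest.fixture(scope="session")
def desk_cohort():
    """Small 2-class synthetic cohort with dFC sequences, shared per session."""
    from dfcmamba.synth import desk_preset, generate_cohort

    cfg = desk_preset(n_classes=2, seed=0)
    cfg.subjects_per_class = 8  # lighter than the acceptance cohort
    sessions, labels, split = generate_cohort(cfg)
    seqs = [build_dfc(ts, DFCConfig()) for ts in sessions]
    return {"cfg": cfg, "sessions": sessions, "labels": labels,
            "split": split, "seqs": seqs}
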