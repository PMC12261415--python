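import numpy as np
import pytest

from protacdeg import pipeline
from protacdeg.config import ModelConfig, TrainConfig
from protacdeg.synthetic import SyntheticConfig, planted_signal_dataset


def small_train_config(**overrides) -> TrainConfig:
    """Down-scaled architecture used throughout the tests so training
    finishes quickly; the planted-signal data conditions are unchanged."""
    model = ModelConfig(d_hidden=32, d_attention=16, n_layers=2, fp_bits=256)
    cfg = TrainConfig(model=model, epochs=30, batch_size=50)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@pytest.fixture(scope="session")
def small_config():
    return small_train_config()


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A 60-sample planted-signal dataset shared across tests."""
    out = tmp_path_factory.mktemp("tiny_dataset")
    manifest, truth = planted_signal_dataset(SyntheticConfig(n_samples=60, seed=7), out)
    cfg = small_train_config()
    samples = pipeline.build_samples(manifest, cfg)
    return {"manifest": manifest, "truth": truth, "samples": samples,
            "config": cfg, "dir": out}
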