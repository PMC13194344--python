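import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from endovlm.model import ModelConfig
from endovlm.synth import GeneratorConfig, build_dataset
from endovlm.textproc import build_vocab


def manifest_corpus(manifest):
    return sorted({t for r in manifest.records
                   for t in (r.description_prev, r.description_current,
                             r.report_target)})


@pytest.fixture(scope="session")
def tiny_manifest(tmp_path_factory):
    """Small but complete synthetic dataset (3 procedures, ~350 frames)."""
    cfg = GeneratorConfig(seed=5, n_procedures=3,
                          activities_per_procedure=(8, 10),
                          activity_duration=(1.5, 3.0),
                          missing_channel_rate=0.05)
    return build_dataset(cfg, tmp_path_factory.mktemp("tiny_ds"))


@pytest.fixture(scope="session")
def tiny_vocab(tiny_manifest):
    return build_vocab(manifest_corpus(tiny_manifest))


@pytest.fixture(scope="session")
def small_model_config(tiny_vocab):
    """Narrow model for unit tests (width 32, 3 conv blocks)."""
    return ModelConfig(embed_dim=32, conv_channels=(8, 16, 32),
                       classifier_hidden=(32, 32), decoder_hidden=32,
                       vocab_size=len(tiny_vocab), n_classes=16)
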