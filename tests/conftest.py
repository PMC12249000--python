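import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from cellsage import (ModelConfig, SyntheticConfig, build_model,
                      extract_stain_profile, generate_dataset)
from cellsage.synthetic import reference_patch


def tiny_config(**overrides) -> ModelConfig:
    """A small config in the reference family, cheap enough for unit tests."""
    kw = dict(input_size=16, mscfe_branch_channels=2, stage_widths=(8, 16),
              blocks_per_stage=1, cbam_reduction_ratio=4, dropout_rate=0.0)
    kw.update(overrides)
    return ModelConfig(**kw)


@pytest.fixture
def tiny_model_config():
    return tiny_config()


@pytest.fixture
def tiny_model(tiny_model_config):
    return build_model(tiny_model_config, seed=7)


@pytest.fixture(scope="session")
def small_synth_config():
    return SyntheticConfig(n_patients_per_class=3, images_per_patient=4, seed=11)


@pytest.fixture(scope="session")
def small_synth_dataset(tmp_path_factory, small_synth_config):
    out = tmp_path_factory.mktemp("synth")
    manifest, index = generate_dataset(small_synth_config, out)
    return manifest, index


@pytest.fixture(scope="session")
def default_profile():
    return extract_stain_profile(reference_patch())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
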