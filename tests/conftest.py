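import numpy as np
import pytest

import scaleformer as sf
from scaleformer import pipeline
from scaleformer.backbone import RandomConvBackbone


@pytest.fixture(scope="session")
def synth_cfg() -> sf.SynthConfig:
    """Study conditions: 40 slides, 4 categories, seed 7."""
    return sf.SynthConfig()


@pytest.fixture(scope="session")
def dataset(synth_cfg) -> sf.SynthDataset:
    return sf.generate_dataset(synth_cfg)


@pytest.fixture(scope="session")
def slices_by_slide(dataset):
    return pipeline.prepare_slices(dataset.slides)


@pytest.fixture(scope="session")
def backbone() -> RandomConvBackbone:
    return RandomConvBackbone(feature_dim=192, seed=0)


@pytest.fixture(scope="session")
def features(slices_by_slide, backbone):
    return pipeline.compute_slice_features(slices_by_slide, backbone)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
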