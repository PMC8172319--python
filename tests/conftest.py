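import numpy as np
import pytest

from vbmnet import synth
from vbmnet.nn import ModelConfig, build_model
from vbmnet.volume_io import PhenotypeRecord, SampleTensor, TissueVolumePair


@pytest.fixture(scope="session")
def tiny_atlas():
    return synth.generate_atlas((16, 16, 16), n_rois=3, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_atlas):
    """Small 16^3 cohort with an age effect in ROI 1 and gender effect in ROI 2."""
    spec = synth.CohortSpec(
        n_subjects=36, shape=(16, 16, 16),
        effects=(synth.EffectSpec("age", (1,), -0.02),
                 synth.EffectSpec("gender", (2,), 0.05)),
        seed=3)
    pairs, phenotypes = synth.generate_cohort(spec, tiny_atlas)
    return pairs, phenotypes


@pytest.fixture()
def tiny_net():
    cfg = ModelConfig(filters_per_block=(2,), dense_units=4, dropout_rate=0.0)
    return build_model(cfg, (8, 8, 8), seed=1)


def random_pair(rng, shape=(8, 8, 8), subject_id="sub-x"):
    gm = rng.uniform(0, 1, shape).astype(np.float32)
    wm = rng.uniform(0, 1, shape).astype(np.float32)
    return TissueVolumePair(subject_id, gm, wm)


def make_sample(values, subject_id="sub-x", age=10.0, gender=0, diagnosis=0):
    return SampleTensor(values, PhenotypeRecord(subject_id, age, gender, diagnosis))
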