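import numpy as np
import pytest
from hypothesis import settings

from ctrsa import StudyConfig, make_implant_model

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def models():
    return {seg: make_implant_model(seg) for seg in ("stem", "cup")}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def quiet_config():
    """Small noiseless study config for deterministic geometry tests."""
    return StudyConfig(
        n_subjects=3,
        noise_sd_ctrsa=0.0,
        noise_sd_mbrsa=0.0,
        point_noise_sd=0.0,
        subject_sd=0.0,
        seed=42,
    )


def random_rigid(rng, max_rot_deg=15.0, max_trans=50.0):
    from ctrsa import RigidTransform

    return RigidTransform.random(rng, max_rot_deg, max_trans)
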