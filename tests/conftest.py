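import numpy as np
import pytest

from torsiongait.cohort import EffectSpec, Subject, generate_cohort, generate_trial
from torsiongait.femur import generate_template_femur
from torsiongait.msk import Posture, build_model


@pytest.fixture(scope="session")
def template_subject():
    """Template-anthropometrics subject: all scale factors are 1."""
    return Subject(
        id="TPL", mass=75.0, height=1.75, sex="M", side="R",
        torsion=5.5, hjc_distance=170.0, walking_speed=5.2,
    )


@pytest.fixture(scope="session")
def baseline_model(template_subject):
    return build_model(template_subject, generate_template_femur(5.5, "R"))


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(5, seed=123)


@pytest.fixture(scope="session")
def clean_trial(template_subject):
    """Noise-free trial with the default torsion coupling."""
    return generate_trial(template_subject, EffectSpec(noise_sd=0.0), seed=7)


@pytest.fixture(scope="session")
def noisy_trial(small_cohort):
    return generate_trial(small_cohort[0], EffectSpec(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def neutral_posture():
    return Posture()
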