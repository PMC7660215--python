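import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def clean_trial():
    """One noise-free trial: ideal mounting, no jitter, exact reference."""
    from tugkin.simulate import StudyDesign, generate_study, zero_mounts

    design = StudyDesign(
        n_subjects=1,
        trials_per_subject=(1,),
        seed=7,
        duration_jitter=0.0,
        ref_noise_sd_deg=0.0,
    )
    return generate_study(design, mounts=zero_mounts())[0]


@pytest.fixture(scope="session")
def clean_records(clean_trial):
    from tugkin.pipeline import study_error_table

    return study_error_table([clean_trial])
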