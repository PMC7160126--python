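import pytest

from haigisl import EyeBiometry, SurgeryCase, default_params_training, generate_cohort


@pytest.fixture
def mean_eye():
    """The training-cohort mean eye: long, flat post-ablation cornea."""
    return EyeBiometry(
        axial_length=28.43, acd=3.62, mean_corneal_radius=8.79, sa8=3.69
    )


@pytest.fixture
def mean_case(mean_eye):
    return SurgeryCase("mean", mean_eye, implanted_power=20.0, postop_se=1.418)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(default_params_training(n=80, seed=42))
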