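import pytest

from multistress.schedule import make_protocol_schedule
from multistress.simulate import (
    SamplingRates,
    SubjectVariability,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def tiny_rates():
    return SamplingRates(ecg=64.0, gsr=32.0, rap=64.0, st=1.0, cortisol_every_s=60.0)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_rates):
    """3 subjects x 2 sessions on a shortened 2-stressor protocol."""
    schedule = make_protocol_schedule(2, 60.0, 60.0)
    return simulate_cohort(
        3, 2, schedule, SubjectVariability.low_noise(), rates=tiny_rates, seed=42
    )


@pytest.fixture(scope="session")
def study_windows():
    """The 15-subject x 2-session large-effect study cohort, windowed."""
    from multistress.presets import make_study_windows

    return make_study_windows(seed=1)


@pytest.fixture(scope="session")
def study_binary_model(study_windows):
    """One binary classifier trained on the full study cohort."""
    from multistress.model import train
    from multistress.presets import fast_model_config

    fusion, block, hp = fast_model_config(0)
    return train(
        study_windows, task="binary", hyperparams=hp, seed=0,
        fusion_config=fusion, block_config=block,
    )


@pytest.fixture(scope="session")
def noiseless_recording(tiny_rates):
    """One noiseless subject on a 3-stressor protocol (ground-truth recovery)."""
    schedule = make_protocol_schedule(3, 120.0, 120.0)
    return simulate_cohort(
        1, 1, schedule, SubjectVariability.noiseless(), rates=tiny_rates, seed=7
    )[0]
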