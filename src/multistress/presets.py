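"""Desk-scale study presets used by the examples and the acceptance script.

The full protocol (15 subjects x 2 sessions, 600-s blocks, 128/64-Hz
channels) produces hours of multi-rate signal; the presets here shrink the
block length and sampling rates — never the cohort size or the protocol
structure — so a complete subject-level LOOCV runs on one CPU in minutes.
"""

from __future__ import annotations

from multistress.dataset import WindowedDataset, normalize_per_session, windows_from_cohort
from multistress.model import FusionConfig, InceptionBlockConfig, TrainHyperparams
from multistress.schedule import make_protocol_schedule
from multistress.simulate import SamplingRates, SubjectVariability, simulate_cohort

#: Reduced sampling rates: ECG at its 64-Hz floor, GSR at 32 Hz.
FAST_RATES = SamplingRates(ecg=64.0, gsr=32.0, rap=64.0, st=1.0, cortisol_every_s=60.0)


def make_study_cohort(
    n_subjects: int = 15,
    n_sessions: int = 2,
    block_s: float = 90.0,
    seed: int = 0,
    variability: SubjectVariability | None = None,
):
    """A large-effect, low-noise cohort on the full 5-stressor protocol."""
    schedule = make_protocol_schedule(5, block_s, block_s)
    var = variability or SubjectVariability.low_noise()
    return simulate_cohort(n_subjects, n_sessions, schedule, var, rates=FAST_RATES, seed=seed)


def make_study_windows(
    seed: int = 0,
    n_subjects: int = 15,
    n_sessions: int = 2,
    block_s: float = 90.0,
    window_s: float = 5.0,
    overlap: float = 0.0,
) -> WindowedDataset:
    """Windowed large-effect cohort for the learning-sanity evaluation.

    Non-overlapping 5-s windows keep the LOOCV affordable; the 50%-overlap
    setting used for production windowing is exercised separately.
    """
    cohort = make_study_cohort(n_subjects, n_sessions, block_s, seed)
    return normalize_per_session(windows_from_cohort(cohort, window_s, overlap))


def fast_model_config(seed: int = 0) -> tuple[FusionConfig, InceptionBlockConfig, TrainHyperparams]:
    """Small single-block model + short training budget for desk-scale runs."""
    fusion = FusionConfig(
        embedding_dim=16, attention_dim=16, head_hidden=32, n_blocks=1,
        input_len=40, seed=seed,
    )
    block = InceptionBlockConfig(n_filters=8)
    hp = TrainHyperparams(lr=3e-3, batch_size=128, max_epochs=10, patience=3)
    return fusion, block, hp
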