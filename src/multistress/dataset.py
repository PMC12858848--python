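"""Model-ready window pipeline: lag alignment, windowing, jitter, scaling.

Recordings are segmented into fixed-length windows (default 5 s with 50%
overlap), labeled from the stressor schedule, z-scored with scalers fitted
on training subjects only, and optionally augmented with Gaussian jitter
(σ = 0.06 in normalized units) applied to the continuous channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from multistress.simulate import SparseChannel, SubjectRecording

CONTINUOUS_MODALITIES = ("ecg", "gsr", "rap", "st")
MODALITIES = CONTINUOUS_MODALITIES + ("cortisol",)
DEFAULT_CORTISOL_LAG_S = 300.0


@dataclass
class WindowedDataset:
    """Fixed-length multimodal windows with labels and provenance IDs.

    ``windows`` maps each continuous modality to an ``(n, T_m)`` array;
    cortisol is the lag-aligned scalar nearest each window's center, stored
    as an ``(n,)`` vector (models broadcast it to a constant channel).
    """

    windows: dict[str, np.ndarray]
    cortisol: np.ndarray
    labels: np.ndarray            # StressState values as strings
    subject_ids: np.ndarray
    session_ids: np.ndarray
    augmented: np.ndarray         # False = original, True = jittered copy
    window_s: float
    sampling_rates: dict[str, float]
    normalized: bool = False

    def __len__(self) -> int:
        return len(self.labels)

    def select(self, mask: np.ndarray) -> "WindowedDataset":
        return replace(
            self,
            windows={m: w[mask] for m, w in self.windows.items()},
            cortisol=self.cortisol[mask],
            labels=self.labels[mask],
            subject_ids=self.subject_ids[mask],
            session_ids=self.session_ids[mask],
            augmented=self.augmented[mask],
        )

    @staticmethod
    def concatenate(parts: list["WindowedDataset"]) -> "WindowedDataset":
        first = parts[0]
        return replace(
            first,
            windows={
                m: np.concatenate([p.windows[m] for p in parts]) for m in first.windows
            },
            cortisol=np.concatenate([p.cortisol for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            subject_ids=np.concatenate([p.subject_ids for p in parts]),
            session_ids=np.concatenate([p.session_ids for p in parts]),
            augmented=np.concatenate([p.augmented for p in parts]),
        )


def count_windows(length_s: float, window_s: float, overlap: float) -> int:
    """Number of windows fitting in a segment: floor((L − W)/stride) + 1."""
    if not (0 <= overlap < 1):
        raise ValueError("overlap must lie in [0, 1)")
    if window_s > length_s:
        return 0
    stride = window_s * (1.0 - overlap)
    return int(np.floor((length_s - window_s) / stride + 1e-9)) + 1


def align_cortisol(recording: SubjectRecording, lag_s: float = DEFAULT_CORTISOL_LAG_S) -> SubjectRecording:
    """Shift the sweat-cortisol timestamps earlier by the sweat-transport lag.

    A sample measured at time t reflects the stressor state at t − lag; the
    shift re-anchors each sample to the moment it physiologically reflects,
    so windowing sees stressor-aligned cortisol values.
    """
    cort = recording.channels["cortisol"]
    if not isinstance(cort, SparseChannel):
        raise TypeError("cortisol channel must be sparse")
    shifted = SparseChannel(cort.times_s - lag_s, cort.values.copy(), cort.units)
    channels = dict(recording.channels)
    channels["cortisol"] = shifted
    return SubjectRecording(recording.subject_id, recording.session_id, channels, recording.schedule)


def make_windows(
    recording: SubjectRecording,
    window_s: float = 5.0,
    overlap: float = 0.5,
    cortisol_lag_s: float = DEFAULT_CORTISOL_LAG_S,
) -> WindowedDataset:
    """Segment one recording into labeled fixed-length windows.

    Windows are laid out per schedule segment (offsets 0, stride, ... from
    the segment start), so no window straddles two states; windows that
    would straddle are simply never generated.  Each window carries the
    lag-aligned cortisol scalar nearest its center.
    """
    if not (0 <= overlap < 1):
        raise ValueError("overlap must lie in [0, 1)")
    stride = window_s * (1.0 - overlap)
    rec = align_cortisol(recording, cortisol_lag_s)
    cort = rec.channels["cortisol"]

    starts, labels = [], []
    for seg in rec.schedule.segments:
        k = count_windows(seg.duration_s, window_s, overlap)
        if k == 0:
            warnings.warn(
                f"segment [{seg.start_s}, {seg.end_s}) shorter than the window; skipped",
                stacklevel=2,
            )
            continue
        starts.extend(seg.start_s + np.arange(k) * stride)
        labels.extend([seg.label.value] * k)
    starts = np.asarray(starts)

    windows: dict[str, np.ndarray] = {}
    rates: dict[str, float] = {}
    for m in CONTINUOUS_MODALITIES:
        ch = rec.channels[m]
        fs = ch.sampling_rate
        w_len = int(round(window_s * fs))
        idx0 = np.round(starts * fs).astype(int)
        idx0 = np.minimum(idx0, max(len(ch.samples) - w_len, 0))
        windows[m] = np.stack([ch.samples[i : i + w_len] for i in idx0]) if len(starts) else np.zeros((0, w_len))
        rates[m] = fs
    centers = starts + window_s / 2.0
    if len(cort.times_s):
        nearest = np.argmin(np.abs(cort.times_s[None, :] - centers[:, None]), axis=1)
        cort_vals = cort.values[nearest]
    else:
        cort_vals = np.zeros(len(starts))

    n = len(starts)
    return WindowedDataset(
        windows=windows,
        cortisol=cort_vals,
        labels=np.asarray(labels, dtype=object),
        subject_ids=np.asarray([recording.subject_id] * n, dtype=object),
        session_ids=np.asarray([recording.session_id] * n, dtype=object),
        augmented=np.zeros(n, dtype=bool),
        window_s=window_s,
        sampling_rates=rates,
    )


def windows_from_cohort(recordings, window_s: float = 5.0, overlap: float = 0.5,
                        cortisol_lag_s: float = DEFAULT_CORTISOL_LAG_S) -> WindowedDataset:
    """Window every recording in a cohort and concatenate."""
    return WindowedDataset.concatenate(
        [make_windows(r, window_s, overlap, cortisol_lag_s) for r in recordings]
    )


@dataclass
class Scalers:
    """Per-modality z-score parameters fitted on training subjects only."""

    means: dict[str, float]
    sds: dict[str, float]

    def to_dict(self) -> dict:
        return {"means": self.means, "sds": self.sds}

    @classmethod
    def from_dict(cls, d: dict) -> "Scalers":
        return cls(dict(d["means"]), dict(d["sds"]))


def fit_scalers(dataset: WindowedDataset) -> Scalers:
    means, sds = {}, {}
    for m in CONTINUOUS_MODALITIES:
        means[m] = float(dataset.windows[m].mean())
        sd = float(dataset.windows[m].std())
        if sd == 0:
            warnings.warn(f"zero-variance channel {m}: using unit divisor", stacklevel=2)
            sd = 1.0
        sds[m] = sd
    means["cortisol"] = float(dataset.cortisol.mean()) if len(dataset) else 0.0
    sd = float(dataset.cortisol.std()) if len(dataset) else 1.0
    sds["cortisol"] = sd if sd > 0 else 1.0
    return Scalers(means, sds)


def normalize(
    dataset: WindowedDataset, scalers: Scalers | None = None
) -> tuple[WindowedDataset, Scalers]:
    """Z-score all modalities; fit scalers if none given (training data only).

    Pass the training-set scalers when transforming validation/test windows
    so no statistic of held-out subjects leaks into the transform.
    """
    if scalers is None:
        scalers = fit_scalers(dataset)
    new_windows = {
        m: (dataset.windows[m] - scalers.means[m]) / scalers.sds[m]
        for m in CONTINUOUS_MODALITIES
    }
    new_cort = (dataset.cortisol - scalers.means["cortisol"]) / scalers.sds["cortisol"]
    return replace(dataset, windows=new_windows, cortisol=new_cort, normalized=True), scalers


def normalize_per_session(dataset: WindowedDataset) -> WindowedDataset:
    """Z-score each (subject, session) group by its own per-modality stats.

    Removes between-subject and between-session baseline offsets (tonic
    level, resting temperature, circadian cortisol anchor) that do not
    transfer across subjects, leaving within-session stressor dynamics.
    Uses only each session's own unlabeled signal statistics, so no
    information crosses subjects and no labels are consulted; apply it
    before the global train-fitted z-score.
    """
    new_windows = {m: w.copy() for m, w in dataset.windows.items()}
    new_cort = dataset.cortisol.copy()
    keys = dataset.subject_ids.astype(str).astype(object) + "|" + dataset.session_ids.astype(str).astype(object)
    for key in np.unique(keys):
        g = keys == key
        for m in CONTINUOUS_MODALITIES:
            mu = dataset.windows[m][g].mean()
            sd = dataset.windows[m][g].std() or 1.0
            new_windows[m][g] = (dataset.windows[m][g] - mu) / sd
        mu = dataset.cortisol[g].mean()
        sd = dataset.cortisol[g].std() or 1.0
        new_cort[g] = (dataset.cortisol[g] - mu) / sd
    return replace(dataset, windows=new_windows, cortisol=new_cort)


def jitter(dataset: WindowedDataset, sigma: float = 0.06, seed: int | None = None) -> WindowedDataset:
    """Append Gaussian-jittered copies of every window (augmentation).

    Noise N(0, σ²) is added to the normalized continuous channels only —
    never to labels, IDs, or the per-window cortisol scalar.  The result has
    exactly twice as many windows, with the copies flagged ``augmented``.
    """
    rng = np.random.default_rng(seed)
    jit_windows = {}
    for m in CONTINUOUS_MODALITIES:
        w = dataset.windows[m]
        jit_windows[m] = np.concatenate([w, w + rng.normal(0.0, sigma, size=w.shape)])
    return replace(
        dataset,
        windows=jit_windows,
        cortisol=np.concatenate([dataset.cortisol, dataset.cortisol]),
        labels=np.concatenate([dataset.labels, dataset.labels]),
        subject_ids=np.concatenate([dataset.subject_ids, dataset.subject_ids]),
        session_ids=np.concatenate([dataset.session_ids, dataset.session_ids]),
        augmented=np.concatenate(
            [dataset.augmented, np.ones(len(dataset), dtype=bool)]
        ),
    )


# ---------------------------------------------------------------------------
# HDF5 serialization
# ---------------------------------------------------------------------------

def save_windows(dataset: WindowedDataset, path) -> None:
    """Serialize a windowed dataset to one HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        for m, w in dataset.windows.items():
            d = f.create_dataset(f"windows/{m}", data=w)
            d.attrs["sampling_rate"] = dataset.sampling_rates[m]
        f.create_dataset("cortisol", data=dataset.cortisol)
        str_dt = "S32"
        f.create_dataset("labels", data=dataset.labels.astype(str_dt))
        f.create_dataset("subject_ids", data=dataset.subject_ids.astype(str_dt))
        f.create_dataset("session_ids", data=dataset.session_ids.astype(str_dt))
        f.create_dataset("augmented", data=dataset.augmented)
        f.attrs["window_s"] = dataset.window_s
        f.attrs["normalized"] = dataset.normalized


def load_windows(path) -> WindowedDataset:
    import h5py

    with h5py.File(path, "r") as f:
        windows = {m: f[f"windows/{m}"][...] for m in f["windows"]}
        rates = {m: float(f[f"windows/{m}"].attrs["sampling_rate"]) for m in windows}
        dec = lambda a: np.asarray([s.decode() for s in a], dtype=object)
        return WindowedDataset(
            windows=windows,
            cortisol=f["cortisol"][...],
            labels=dec(f["labels"][...]),
            subject_ids=dec(f["subject_ids"][...]),
            session_ids=dec(f["session_ids"][...]),
            augmented=f["augmented"][...].astype(bool),
            window_s=float(f.attrs["window_s"]),
            sampling_rates=rates,
            normalized=bool(f.attrs["normalized"]),
        )
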