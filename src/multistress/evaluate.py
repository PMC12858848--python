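"""Subject-level cross-validation and agreement statistics.

Subject-independent evaluation uses leave-one-subject-out cross-validation
(one fold per subject; an inner subject is held out for validation and early
stopping, and normalization statistics are fitted on training subjects
only).  Subject-dependent evaluation fine-tunes only the decision head on
one session of the target subject and tests on the other.  Agreement between
paired measurement series is quantified by the squared Pearson correlation
and Bland–Altman limits of agreement at 1.96 standard deviations of the
differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score

from multistress.dataset import WindowedDataset, normalize
from multistress.model import (
    TrainHyperparams,
    fine_tune_head,
    predict,
    task_labels,
    train,
)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-fold metrics plus pooled confusion counts."""

    task: str
    fold_accuracy_pct: list[float] = field(default_factory=list)
    fold_f1_pct: list[float] = field(default_factory=list)
    fold_subjects: list[str] = field(default_factory=list)
    confusion: np.ndarray | None = None
    class_names: list[str] = field(default_factory=list)

    @property
    def mean_accuracy_pct(self) -> float:
        return float(np.mean(self.fold_accuracy_pct))

    @property
    def sd_accuracy_pct(self) -> float:
        return float(np.std(self.fold_accuracy_pct, ddof=1)) if len(self.fold_accuracy_pct) > 1 else 0.0

    @property
    def mean_f1_pct(self) -> float:
        return float(np.mean(self.fold_f1_pct))

    @property
    def sd_f1_pct(self) -> float:
        return float(np.std(self.fold_f1_pct, ddof=1)) if len(self.fold_f1_pct) > 1 else 0.0

    def summary(self) -> str:
        return (
            f"{self.task}: accuracy {self.mean_accuracy_pct:.3f}% ± {self.sd_accuracy_pct:.3f}%, "
            f"F1 {self.mean_f1_pct:.3f}% ± {self.sd_f1_pct:.3f}% over {len(self.fold_accuracy_pct)} folds"
        )


@dataclass
class AgreementReport:
    """Bland–Altman agreement summary for paired measurements."""

    r_squared: float
    mean_difference: float
    sd_differences: float
    loa_lower: float
    loa_upper: float
    n: int
    means: np.ndarray = field(default_factory=lambda: np.array([]))
    differences: np.ndarray = field(default_factory=lambda: np.array([]))


# ---------------------------------------------------------------------------
# basic metrics
# ---------------------------------------------------------------------------

def metrics(true_labels, predicted_labels, class_names: list[str] | None = None):
    """Accuracy (%), macro-F1 (%), and the confusion matrix (true × predicted)."""
    t = np.asarray(true_labels).astype(str)
    p = np.asarray(predicted_labels).astype(str)
    names = class_names or sorted(set(t) | set(p))
    acc = 100.0 * accuracy_score(t, p)
    f1 = 100.0 * f1_score(t, p, labels=names, average="macro", zero_division=0)
    cm = confusion_matrix(t, p, labels=names)
    return acc, f1, cm


def r_squared(x, y) -> float:
    """Squared Pearson correlation between a reference and a test series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("series must be paired with N >= 2")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("r_squared undefined for a zero-variance series")
    r = np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy)
    return float(r**2)


def bland_altman(x, y) -> AgreementReport:
    """Bland–Altman agreement: differences vs means with 1.96·σ_D limits.

    D_i = y_i − x_i; the limits of agreement are D̄ ± 1.96·σ_D with σ_D the
    sample SD (N−1 denominator).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("Bland–Altman needs paired series with N >= 3")
    d = y - x
    dbar = float(d.mean())
    sd = float(d.std(ddof=1))
    try:
        r2 = r_squared(x, y)
    except ValueError:
        r2 = float("nan")
    return AgreementReport(
        r_squared=r2,
        mean_difference=dbar,
        sd_differences=sd,
        loa_lower=dbar - 1.96 * sd,
        loa_upper=dbar + 1.96 * sd,
        n=len(d),
        means=(x + y) / 2.0,
        differences=d,
    )


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def default_trainer(train_ds, val_ds, seed, task, **train_kwargs):
    return train(train_ds, task=task, seed=seed, val_dataset=val_ds, **train_kwargs)


def loocv_subject_independent(
    dataset: WindowedDataset,
    task: str = "binary",
    trainer=None,
    seed: int = 0,
    hyperparams: TrainHyperparams | None = None,
    shuffle_labels: bool = False,
    subjects_subset: list[str] | None = None,
    **train_kwargs,
) -> EvalReport:
    """Leave-one-subject-out cross-validation (subject-independent).

    One fold per subject: the held-out subject's windows contribute nothing
    to training, inner validation, or normalization.  Within each fold one
    of the remaining subjects is randomly selected for inner validation.
    ``shuffle_labels`` permutes the *training* labels per fold (negative
    control: held-out accuracy should drop to chance).  ``subjects_subset``
    restricts which subjects serve as held-out folds (all still participate
    in training when not held out).
    """
    subjects = list(np.unique(dataset.subject_ids))
    if len(subjects) < 3:
        raise ValueError("subject-level LOOCV needs >= 3 subjects")
    rng = np.random.default_rng(seed)
    folds = subjects_subset or subjects
    report = EvalReport(task=task)
    pooled_cm = None
    class_names: list[str] = []
    for fold_i, held_out in enumerate(folds):
        test_mask = dataset.subject_ids == held_out
        rest = dataset.select(~test_mask)
        test_ds = dataset.select(test_mask)

        ty, _, tkeep = task_labels(test_ds, task)
        if len(np.unique(ty[tkeep])) < 2:
            warnings.warn(f"fold {held_out}: single-class test labels; skipped", stacklevel=2)
            continue

        inner_subjects = list(np.unique(rest.subject_ids))
        val_subject = inner_subjects[rng.integers(len(inner_subjects))]
        val_mask = rest.subject_ids == val_subject
        val_ds = rest.select(val_mask)
        train_ds = rest.select(~val_mask)

        if shuffle_labels:
            perm = rng.permutation(len(train_ds))
            train_ds = _with_labels(train_ds, train_ds.labels[perm])

        train_norm, scalers = normalize(train_ds)
        val_norm, _ = normalize(val_ds, scalers)
        fold_seed = int(rng.integers(2**31 - 1))
        if trainer is not None:
            model = trainer(train_norm, val_norm, fold_seed, task)
        else:
            model = train(
                train_norm, task=task, seed=fold_seed, val_dataset=val_norm,
                hyperparams=hyperparams, scalers=scalers, **train_kwargs,
            )
            model.scalers = scalers
        test_norm, _ = normalize(test_ds, scalers)
        pred, _, _ = predict(model, test_norm)
        keep_idx = np.where(tkeep)[0]
        truth = (
            _binary_names(test_ds.labels[keep_idx])
            if task == "binary"
            else test_ds.labels[keep_idx]
        )
        acc, f1, cm = metrics(truth, pred[keep_idx], class_names=model.label_vocab)
        report.fold_accuracy_pct.append(acc)
        report.fold_f1_pct.append(f1)
        report.fold_subjects.append(str(held_out))
        class_names = model.label_vocab
        pooled_cm = cm if pooled_cm is None else pooled_cm + cm
    report.confusion = pooled_cm
    report.class_names = class_names
    return report


def _binary_names(labels: np.ndarray) -> np.ndarray:
    return np.where(np.asarray(labels).astype(str) == "rest", "rest", "stress")


def _with_labels(ds: WindowedDataset, labels: np.ndarray) -> WindowedDataset:
    from dataclasses import replace

    return replace(ds, labels=labels)


def evaluate_subject_dependent(
    dataset: WindowedDataset,
    target_subject: str,
    task: str = "binary",
    seed: int = 0,
    hyperparams: TrainHyperparams | None = None,
    fine_tune_epochs: int = 10,
    **train_kwargs,
) -> EvalReport:
    """Subject-dependent evaluation with head-only fine-tuning.

    A base model is trained on all other subjects, its decision head is
    fine-tuned on one session of the target subject, and the model is tested
    on the target subject's remaining session.  Encoder weights are verified
    unchanged by the fine-tune.
    """
    t_mask = dataset.subject_ids == target_subject
    target_ds = dataset.select(t_mask)
    sessions = list(np.unique(target_ds.session_ids))
    if len(sessions) < 2:
        raise ValueError(f"subject {target_subject} needs >= 2 sessions")
    rest = dataset.select(~t_mask)
    train_norm, scalers = normalize(rest)
    model = train(
        train_norm, task=task, seed=seed, hyperparams=hyperparams,
        scalers=scalers, **train_kwargs,
    )
    model.scalers = scalers

    tune_ds = target_ds.select(target_ds.session_ids == sessions[0])
    test_ds = target_ds.select(target_ds.session_ids == sessions[1])

    before = model.net.encoder_checksum()
    tuned = fine_tune_head(model, tune_ds, epochs=fine_tune_epochs, seed=seed)
    after = tuned.net.encoder_checksum()
    if abs(before - after) > 1e-9:
        raise AssertionError("encoder weights changed during head-only fine-tune")

    ty, _, tkeep = task_labels(test_ds, task)
    pred, _, _ = predict(tuned, test_ds)
    truth = (
        _binary_names(test_ds.labels[tkeep]) if task == "binary" else test_ds.labels[tkeep]
    )
    acc, f1, cm = metrics(truth, pred[tkeep], class_names=tuned.label_vocab)
    return EvalReport(
        task=f"{task}-subject-dependent",
        fold_accuracy_pct=[acc],
        fold_f1_pct=[f1],
        fold_subjects=[str(target_subject)],
        confusion=cm,
        class_names=tuned.label_vocab,
    )
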