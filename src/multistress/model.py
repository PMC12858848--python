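"""Inception-style multimodal attention-fusion stress classifier.

Each of the five modalities (ECG, GSR, RAP, ST, cortisol) is encoded by a
stack of 1-D Inception blocks (parallel kernel lengths 1/3/5 plus a pooled
path) followed by global average pooling and a dense projection to a common
embedding dimension.  A soft-attention layer scores the five embeddings,
softmax-normalizes the scores into per-example modality weights, and fuses
the embeddings as their weighted sum; a small dense head maps the fused
vector to class logits.  Two tasks are supported: binary stress-vs-rest and
stress-subtype classification (with or without the rest class).

Windows of different native sampling rates are linearly resampled to a
common input length; the per-window cortisol scalar and other low-rate
channels enter as constant-valued channels on the same grid.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from multistress.dataset import CONTINUOUS_MODALITIES, Scalers, WindowedDataset, normalize
from multistress.nn import (
    Adam,
    Dense,
    GlobalAvgPool,
    InceptionBlock,
    ReLU,
    Sequential,
    SoftAttention,
    cross_entropy,
    softmax,
)

MODALITY_ORDER = ("ecg", "gsr", "rap", "st", "cortisol")

TASKS = ("binary", "subtype", "sixstate")


@dataclass
class InceptionBlockConfig:
    """Configuration of one Inception block (kernels fixed at 1/3/5 + pool)."""

    n_filters: int = 8
    kernel_lengths: tuple[int, ...] = (1, 3, 5)
    activation: str = "relu"
    padding: str = "same"

    @property
    def out_channels(self) -> int:
        return 4 * self.n_filters


@dataclass
class FusionConfig:
    """Architecture of the five-branch attention-fusion network."""

    modalities: tuple[str, ...] = MODALITY_ORDER
    embedding_dim: int = 16
    attention_dim: int = 16
    head_hidden: int = 32
    n_blocks: int = 1
    input_len: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if tuple(sorted(self.modalities)) != tuple(sorted(MODALITY_ORDER)):
            raise ValueError(f"modalities must be exactly {set(MODALITY_ORDER)}")


@dataclass
class TrainHyperparams:
    lr: float = 3e-3
    batch_size: int = 128
    max_epochs: int = 10
    patience: int = 3
    grid: list[dict] | None = None  # optional overrides searched on inner val


class StressNet:
    """The numpy network: per-modality encoders, soft attention, dense head."""

    def __init__(self, cfg: FusionConfig, block_cfg: InceptionBlockConfig, n_classes: int):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.block_cfg = block_cfg
        self.n_classes = n_classes
        self.encoders: dict[str, Sequential] = {}
        for m in MODALITY_ORDER:
            layers = []
            c_in = 1
            for _ in range(cfg.n_blocks):
                layers.append(InceptionBlock(c_in, block_cfg.n_filters, rng))
                c_in = block_cfg.out_channels
            layers += [GlobalAvgPool(), Dense(c_in, cfg.embedding_dim, rng), ReLU()]
            self.encoders[m] = Sequential(layers)
        self.fusion = SoftAttention(cfg.embedding_dim, cfg.attention_dim, rng)
        self.head = Sequential(
            [Dense(cfg.embedding_dim, cfg.head_hidden, rng), ReLU(),
             Dense(cfg.head_hidden, n_classes, rng)]
        )

    # -- parameter groups ---------------------------------------------------
    def encoder_params(self):
        out = []
        for m in MODALITY_ORDER:
            out.extend(self.encoders[m].params())
        out.extend(self.fusion.params())
        return out

    def head_params(self):
        return self.head.params()

    def params(self):
        return self.encoder_params() + self.head_params()

    def encoder_checksum(self) -> float:
        """Deterministic fingerprint of all non-head parameters."""
        return float(sum(np.abs(p.value).sum() for p in self.encoder_params()))

    # -- forward / backward -------------------------------------------------
    def forward(self, inputs: dict[str, np.ndarray], ablate: str | None = None) -> np.ndarray:
        """Class logits; ``ablate`` zeroes one modality's embedding before
        fusion (modality-removal surgery for interpretability checks)."""
        embs = [self.encoders[m].forward(inputs[m]) for m in MODALITY_ORDER]
        E = np.stack(embs, axis=1)  # (B, M, d)
        if ablate is not None:
            E = E.copy()
            E[:, MODALITY_ORDER.index(ablate), :] = 0.0
        fused = self.fusion.forward(E)
        return self.head.forward(fused)

    def backward(self, dlogits: np.ndarray) -> None:
        dfused = self.head.backward(dlogits)
        dE = self.fusion.backward(dfused)
        for i, m in enumerate(MODALITY_ORDER):
            self.encoders[m].backward(dE[:, i])

    @property
    def attention_weights(self) -> np.ndarray:
        return self.fusion.alpha


@dataclass
class TrainedModel:
    """A trained classifier plus everything needed to reproduce predictions."""

    net: StressNet
    fusion_config: FusionConfig
    block_config: InceptionBlockConfig
    label_vocab: list[str]
    task: str
    scalers: Scalers | None = None
    training_log: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# input preparation and labels
# ---------------------------------------------------------------------------

def _resample_rows(w: np.ndarray, target_len: int) -> np.ndarray:
    """Linear resampling of each row to ``target_len`` samples."""
    n, t = w.shape
    if t == target_len:
        return w
    if t == 1:
        return np.repeat(w, target_len, axis=1)
    xq = np.linspace(0.0, t - 1.0, target_len)
    i0 = np.floor(xq).astype(int)
    i1 = np.minimum(i0 + 1, t - 1)
    frac = xq - i0
    return w[:, i0] * (1.0 - frac) + w[:, i1] * frac


def prepare_inputs(dataset: WindowedDataset, input_len: int) -> dict[str, np.ndarray]:
    """Resample all modalities to (B, 1, input_len) network inputs."""
    inputs = {}
    for m in CONTINUOUS_MODALITIES:
        inputs[m] = _resample_rows(dataset.windows[m], input_len)[:, None, :]
    inputs["cortisol"] = np.repeat(dataset.cortisol[:, None, None], input_len, axis=2)
    return inputs


def task_labels(dataset: WindowedDataset, task: str) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Map window labels to task classes.

    Returns (integer labels, vocabulary, keep-mask).  ``binary`` pools all
    stressors against rest; ``subtype`` classifies the five stressor
    categories (rest windows dropped); ``sixstate`` keeps all six states.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    labels = dataset.labels
    if task == "binary":
        vocab = ["rest", "stress"]
        y = np.where(labels == "rest", 0, 1)
        keep = np.ones(len(labels), dtype=bool)
    elif task == "subtype":
        keep = labels != "rest"
        vocab = sorted(set(labels[keep]))
        lut = {l: i for i, l in enumerate(vocab)}
        y = np.array([lut.get(l, -1) for l in labels])
    else:
        keep = np.ones(len(labels), dtype=bool)
        vocab = sorted(set(labels))
        lut = {l: i for i, l in enumerate(vocab)}
        y = np.array([lut[l] for l in labels])
    return y, vocab, keep


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _epoch_loss(net: StressNet, inputs, y, batch_size=512) -> float:
    total, n = 0.0, len(y)
    for i in range(0, n, batch_size):
        sl = slice(i, min(i + batch_size, n))
        logits = net.forward({m: x[sl] for m, x in inputs.items()})
        loss, _ = cross_entropy(logits, y[sl])
        total += loss * (sl.stop - sl.start)
    return total / n


def _fit(net, inputs, y, val_inputs, val_y, hp: TrainHyperparams, rng) -> list[dict]:
    opt = Adam(net.params(), lr=hp.lr)
    n = len(y)
    best_val, best_state, wait, log = np.inf, None, 0, []
    for epoch in range(hp.max_epochs):
        order = rng.permutation(n)
        ep_loss, nb = 0.0, 0
        for i in range(0, n, hp.batch_size):
            idx = order[i : i + hp.batch_size]
            opt.zero_grad()
            logits = net.forward({m: x[idx] for m, x in inputs.items()})
            loss, dlogits = cross_entropy(logits, y[idx])
            net.backward(dlogits)
            opt.step()
            ep_loss += loss
            nb += 1
        val_loss = _epoch_loss(net, val_inputs, val_y) if len(val_y) else ep_loss / nb
        log.append({"epoch": epoch, "train_loss": ep_loss / nb, "val_loss": val_loss})
        if val_loss < best_val - 1e-5:
            best_val, wait = val_loss, 0
            best_state = [p.value.copy() for p in net.params()]
        else:
            wait += 1
            if wait >= hp.patience:
                break
    if best_state is not None:
        for p, v in zip(net.params(), best_state):
            p.value[...] = v
    return log


def train(
    dataset: WindowedDataset,
    task: str = "binary",
    hyperparams: TrainHyperparams | None = None,
    seed: int = 0,
    fusion_config: FusionConfig | None = None,
    block_config: InceptionBlockConfig | None = None,
    val_dataset: WindowedDataset | None = None,
    scalers: Scalers | None = None,
) -> TrainedModel:
    """Train the attention-fusion classifier on a windowed dataset.

    If no validation set is given, one subject is held out as the inner
    validation split (requires >= 2 subjects).  Training is deterministic
    given ``seed``; early stopping monitors the inner-validation loss.
    An optional hyperparameter grid (``hyperparams.grid``) is searched by
    inner-validation loss.
    """
    hp = hyperparams or TrainHyperparams()
    cfg = fusion_config or FusionConfig(seed=seed)
    bcfg = block_config or InceptionBlockConfig()
    rng = np.random.default_rng(seed)

    if not dataset.normalized:
        dataset, scalers = normalize(dataset, scalers)

    if val_dataset is None:
        subjects = np.unique(dataset.subject_ids)
        if len(subjects) < 2:
            raise ValueError("need >= 2 subjects for the inner validation split")
        val_subject = rng.choice(subjects)
        val_mask = dataset.subject_ids == val_subject
        val_dataset = dataset.select(val_mask)
        dataset = dataset.select(~val_mask)
    elif not val_dataset.normalized:
        val_dataset, _ = normalize(val_dataset, scalers)

    y, vocab, keep = task_labels(dataset, task)
    if len(np.unique(y[keep])) < 2:
        raise ValueError("training labels contain a single class")
    train_ds = dataset.select(keep)
    y = y[keep]
    vy, _, vkeep = task_labels(val_dataset, task)
    val_ds = val_dataset.select(vkeep)
    vy = vy[vkeep]

    inputs = prepare_inputs(train_ds, cfg.input_len)
    val_inputs = prepare_inputs(val_ds, cfg.input_len)

    candidates = [{}] if not hp.grid else hp.grid
    best = None
    for overrides in candidates:
        cand_cfg = FusionConfig(**{
            **asdict(cfg),
            **{k: v for k, v in overrides.items() if k in FusionConfig.__dataclass_fields__},
        })
        cand_bcfg = InceptionBlockConfig(**{
            **asdict(bcfg),
            **{k: v for k, v in overrides.items() if k in InceptionBlockConfig.__dataclass_fields__},
        })
        net = StressNet(cand_cfg, cand_bcfg, len(vocab))
        log = _fit(net, inputs, y, val_inputs, vy, hp, np.random.default_rng(seed + 1))
        val_loss = min(e["val_loss"] for e in log) if log else np.inf
        if best is None or val_loss < best[0]:
            best = (val_loss, net, cand_cfg, cand_bcfg, log)
    _, net, cfg, bcfg, log = best
    return TrainedModel(net, cfg, bcfg, vocab, task, scalers, log)


def fine_tune_head(
    model: TrainedModel,
    dataset: WindowedDataset,
    epochs: int = 10,
    lr: float = 3e-3,
    seed: int = 0,
) -> TrainedModel:
    """Update only the decision head on new data; encoders stay frozen."""
    tuned = TrainedModel(
        net=copy.deepcopy(model.net),
        fusion_config=model.fusion_config,
        block_config=model.block_config,
        label_vocab=model.label_vocab,
        task=model.task,
        scalers=model.scalers,
        training_log=list(model.training_log),
    )
    if not dataset.normalized:
        dataset, _ = normalize(dataset, model.scalers)
    y, vocab, keep = task_labels(dataset, model.task)
    ds = dataset.select(keep)
    y = y[keep]
    inputs = prepare_inputs(ds, tuned.fusion_config.input_len)
    opt = Adam(tuned.net.head_params(), lr=lr)
    rng = np.random.default_rng(seed)
    for _ in range(epochs):
        order = rng.permutation(len(y))
        for i in range(0, len(y), 128):
            idx = order[i : i + 128]
            opt.zero_grad()
            logits = tuned.net.forward({m: x[idx] for m, x in inputs.items()})
            _, dlogits = cross_entropy(logits, y[idx])
            dfused = tuned.net.head.backward(dlogits)  # head grads only
            opt.step()
    return tuned


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict(
    model: TrainedModel, dataset: WindowedDataset, batch_size: int = 1024,
    ablate: str | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Predict labels for windows.

    Returns ``(labels, probabilities, attention_weights)`` where labels are
    vocabulary strings, probabilities are (n, n_classes) rows summing to 1,
    and attention weights are (n, 5) rows over the modality order.
    ``ablate`` removes one modality at the fusion stage (embedding zeroed).
    """
    if not dataset.normalized:
        dataset, _ = normalize(dataset, model.scalers)
    inputs = prepare_inputs(dataset, model.fusion_config.input_len)
    probs, alphas = [], []
    n = len(dataset)
    for i in range(0, n, batch_size):
        sl = slice(i, min(i + batch_size, n))
        logits = model.net.forward({m: x[sl] for m, x in inputs.items()}, ablate=ablate)
        probs.append(softmax(logits))
        alphas.append(model.net.attention_weights.copy())
    probs = np.concatenate(probs) if probs else np.zeros((0, len(model.label_vocab)))
    alphas = np.concatenate(alphas) if alphas else np.zeros((0, len(MODALITY_ORDER)))
    labels = np.asarray([model.label_vocab[i] for i in probs.argmax(axis=1)], dtype=object)
    return labels, probs, alphas


def majority_vote_by_segment(
    labels: np.ndarray, subject_ids: np.ndarray, session_ids: np.ndarray, true_labels: np.ndarray
) -> list[tuple[str, str]]:
    """Aggregate window predictions to one (true, predicted) pair per
    contiguous same-label run within a session (segment-level voting)."""
    out = []
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while (
            j < n
            and subject_ids[j] == subject_ids[i]
            and session_ids[j] == session_ids[i]
            and true_labels[j] == true_labels[i]
        ):
            j += 1
        seg_preds = labels[i:j]
        vals, counts = np.unique(seg_preds.astype(str), return_counts=True)
        out.append((str(true_labels[i]), str(vals[np.argmax(counts)])))
        i = j
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> None:
    """Save weights (npz) plus a JSON config sidecar."""
    path = Path(path)
    arrays = {f"p{i}": p.value for i, p in enumerate(model.net.params())}
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "fusion_config": asdict(model.fusion_config),
        "block_config": asdict(model.block_config),
        "label_vocab": model.label_vocab,
        "task": model.task,
        "scalers": model.scalers.to_dict() if model.scalers else None,
        "training_log": model.training_log,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    fc = sidecar["fusion_config"]
    fc["modalities"] = tuple(fc["modalities"])
    cfg = FusionConfig(**fc)
    bc = sidecar["block_config"]
    bc["kernel_lengths"] = tuple(bc["kernel_lengths"])
    bcfg = InceptionBlockConfig(**bc)
    net = StressNet(cfg, bcfg, len(sidecar["label_vocab"]))
    data = np.load(path.with_suffix(".npz"))
    for i, p in enumerate(net.params()):
        p.value[...] = data[f"p{i}"]
    scalers = Scalers.from_dict(sidecar["scalers"]) if sidecar["scalers"] else None
    return TrainedModel(
        net, cfg, bcfg, sidecar["label_vocab"], sidecar["task"], scalers,
        sidecar["training_log"],
    )
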