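"""Shared supervised training loop for the detector.

All training arms (supervised, federated local steps, finetuning, continual
candidates) run this loop: Adam on a class-balanced cross-entropy, early
stopping on validation AUROC, optionally augmented with a continual-learning
regularizer.  The LwF distillation term enters the loss graph (its gradient
flows through the network); the EWC/MAS quadratic anchors are added to the
gradient analytically (2λw⊙(θ−θ_old) — exact, since they are quadratic in θ).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad, nn
from .autodiff import Tensor
from .cl_methods import MethodState, distillation_ce, penalty_gradient
from .datasets import SiteDataset
from .metrics import auroc
from .model import Detector, demographics_matrix, predict_proba, waveform_batch


@dataclass
class TrainSettings:
    epochs: int = 100
    patience: int = 10
    lr: float = 1e-4
    batch_size: int = 256
    seed: int = 0

    @classmethod
    def paper_scale(cls, seed: int = 0) -> "TrainSettings":
        return cls(epochs=100, patience=10, lr=1e-4, batch_size=256, seed=seed)

    @classmethod
    def tiny(cls, seed: int = 0) -> "TrainSettings":
        return cls(epochs=25, patience=6, lr=1e-3, batch_size=32, seed=seed)


@dataclass
class TrainResult:
    params: np.ndarray                   # flat best-validation parameters θ
    state: dict = field(default_factory=dict)  # full named groups incl. buffers
    best_val_metric: float = 0.0         # validation AUROC p
    hyperparams: dict = field(default_factory=dict)
    epochs_run: int = 0
    decay_trace: list = field(default_factory=list)  # [(λ, val metric), ...]
    log: list = field(default_factory=list)          # per-epoch records

    def __post_init__(self):
        if not 0.0 <= self.best_val_metric <= 1.0:
            raise ValueError("best_val_metric must lie in [0, 1]")


def balanced_class_weights(train_records) -> np.ndarray:
    """Per-class weights N / count(class), from the training partition."""
    labels = np.array([r.label for r in train_records])
    n = len(labels)
    counts = np.array([(labels == c).sum() for c in (0, 1)])
    if (counts == 0).any():
        raise ValueError("both classes must be present in the training partition")
    return n / counts


def balanced_ce_loss(logits, labels, class_weights):
    """Σ_i w_{y_i} · CE_i with weights from the *training partition* counts.

    Accepts a logits Tensor (returns a Tensor) or numpy array (returns float).
    """
    labels = np.asarray(labels, dtype=int)
    w = np.asarray(class_weights, dtype=float)[labels]
    if isinstance(logits, Tensor):
        logp = ad.log_softmax(logits, axis=1)
        picked = ad.sum_(logp * Tensor(np.eye(logits.shape[1])[labels]), axis=1)
        return ad.sum_(Tensor(-w) * picked)
    logits = np.asarray(logits, dtype=float)
    shifted = logits - logits.max(axis=1, keepdims=True)
    logp = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    return float(np.sum(-w * logp[np.arange(len(labels)), labels]))


def evaluate_auroc(model: Detector, records, batch_size: int = 64) -> float:
    """AUROC of the arrhythmia probability over a list of records."""
    scores = []
    for i in range(0, len(records), batch_size):
        chunk = records[i:i + batch_size]
        probs = predict_proba(model, waveform_batch(chunk), demographics_matrix(chunk))
        scores.append(probs[:, 1])
    return auroc(np.concatenate(scores), [r.label for r in records])


def train_detector(model: Detector, site: SiteDataset,
                   settings: TrainSettings,
                   method_state: MethodState | None = None) -> TrainResult:
    """Train in place; returns the best-validation snapshot and its AUROC."""
    train_recs = site.subset("train")
    val_recs = site.subset("val")
    if not train_recs or not val_recs:
        raise ValueError("train and val partitions must be nonempty")
    weights = balanced_class_weights(train_recs)
    rng = np.random.default_rng(np.random.SeedSequence([settings.seed, 0x7124]))
    opt = nn.Adam(model.parameters(), lr=settings.lr)
    params = model.parameters()

    old_model = None
    if method_state is not None and method_state.method_id == "LwF":
        old_model = Detector(model.config)
        old_model.load_state_dict(method_state.old_model_state)
        old_model.eval()

    best_metric, best_flat, best_state, best_epoch = -np.inf, None, None, 0
    log = []
    for epoch in range(settings.epochs):
        order = rng.permutation(len(train_recs))
        for i in range(0, len(order), settings.batch_size):
            batch = [train_recs[j] for j in order[i:i + settings.batch_size]]
            wave = Tensor(waveform_batch(batch))
            demo = Tensor(demographics_matrix(batch))
            labels = [r.label for r in batch]

            logits = model(wave, demo)
            loss = balanced_ce_loss(logits, labels, weights) * Tensor(1.0 / len(batch))
            if old_model is not None:
                with ad.no_grad():
                    old_probs = ad.softmax(old_model(wave, demo), axis=1).data
                cur_probs = ad.softmax(logits, axis=1)
                loss = loss + Tensor(method_state.lam) * distillation_ce(
                    old_probs, cur_probs, method_state.temperature)
            grads = ad.grad(loss, params)

            if method_state is not None and method_state.method_id in ("EWC", "MAS"):
                pen = penalty_gradient(nn.flatten_params(model), method_state)
                k = 0
                for g, p in zip(grads, params):
                    g.data += pen[k:k + p.size].reshape(p.shape)
                    k += p.size
            opt.step(grads)

        val_metric = evaluate_auroc(model, val_recs)
        log.append({"epoch": epoch, "val_auroc": val_metric})
        if val_metric > best_metric:
            best_metric, best_epoch = val_metric, epoch
            best_flat, best_state = nn.flatten_params(model), model.state_dict()
        if epoch - best_epoch >= settings.patience:
            break

    model.load_state_dict(best_state)
    return TrainResult(params=best_flat, state=best_state,
                       best_val_metric=float(best_metric),
                       hyperparams={"lr": settings.lr, "batch_size": settings.batch_size},
                       epochs_run=epoch + 1, log=log)
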