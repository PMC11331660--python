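"""Regularization-based continual-learning method candidates.

Three candidates are implemented, all operating on the detector's flat
parameter vector θ:

* **LwF** — adds a knowledge-distillation cross-entropy between the frozen
  previous model's probabilities on the *current* site's inputs (recorded at
  the start of each epoch) and the training model's probabilities, both
  temperature-softened.  With a shared binary head at every site, the
  "old-task outputs" are simply the previous model's probabilities.
* **EWC** — quadratic anchor λ Σ_i F_i (θ_i − θ_old,i)², with F the diagonal
  empirical Fisher information: the mean squared gradient of log p(y|x; θ)
  at the ground-truth label.
* **MAS** — the same quadratic anchor with importance Ω_i, the mean absolute
  gradient of the squared ℓ2 norm of the model's pre-softmax output
  (post-softmax norms are nearly constant, carrying no importance signal).

Importances are (re-)estimated at each site on that site's data and replace
the previous ones by default (``accumulate="replace"``), mirroring a
per-institution state hand-off; summation is available via
``accumulate="sum"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad, nn
from .autodiff import Tensor

METHODS = ("LwF", "EWC", "MAS")


@dataclass
class MethodState:
    """Everything a continual-learning method carries between institutions."""

    method_id: str
    theta_old: np.ndarray                 # flat parameter snapshot θ_old
    lam: float = 1.0
    temperature: float = 10.0
    fisher: np.ndarray | None = None      # EWC importance F_i ≥ 0
    omega: np.ndarray | None = None       # MAS importance Ω_i ≥ 0
    old_model_state: dict | None = None   # frozen previous model (LwF)

    def __post_init__(self):
        if self.method_id not in METHODS:
            raise ValueError(f"unknown method {self.method_id!r}; expected one of {METHODS}")
        if self.lam < 0 or self.temperature <= 0:
            raise ValueError("λ must be ≥ 0 and T > 0")
        for name in ("fisher", "omega"):
            w = getattr(self, name)
            if w is not None and w.shape != self.theta_old.shape:
                raise ValueError(f"{name} index space does not match theta_old")


# ---------------------------------------------------------------------------
# LwF
# ---------------------------------------------------------------------------

def distill(probs, temperature: float):
    """Temperature-soften a probability vector: p_i^(1/T) / Σ_j p_j^(1/T)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if isinstance(probs, Tensor):
        powered = probs ** (1.0 / temperature)
        return powered / ad.sum_(powered, axis=-1, keepdims=True)
    p = np.asarray(probs, dtype=float)
    if np.all(p == 0):
        raise ValueError("cannot distill a zero vector")
    powered = p ** (1.0 / temperature)
    return powered / powered.sum(axis=-1, keepdims=True)


def distillation_ce(old_probs, current_probs, temperature: float, eps: float = 1e-12):
    """Batch-averaged cross-entropy −Σ_i distill(y_o)^(i) log distill(ŷ_o)^(i)."""
    soft_old = distill(old_probs, temperature)
    soft_cur = distill(current_probs, temperature)
    if isinstance(soft_cur, Tensor):
        old_const = soft_old if isinstance(soft_old, np.ndarray) else soft_old.data
        ce = -ad.sum_(Tensor(old_const) * ad.log(soft_cur + Tensor(eps)), axis=-1)
        return ad.mean_(ce)
    return float(np.mean(-(soft_old * np.log(soft_cur + eps)).sum(axis=-1)))


def lwf_loss(new_task_loss, old_recorded, old_current, lam: float,
             temperature: float):
    """L_new + λ · distillation cross-entropy, batch-averaged.

    ``old_recorded`` are the frozen previous model's probabilities on the
    current batch; ``old_current`` the training model's current probabilities.
    Accepts numpy arrays (returns float) or Tensors (returns a Tensor for
    backprop).
    """
    recorded = np.atleast_2d(old_recorded.data if isinstance(old_recorded, Tensor)
                             else np.asarray(old_recorded, dtype=float))
    current = (old_current if isinstance(old_current, Tensor)
               else np.atleast_2d(np.asarray(old_current, dtype=float)))
    cur_rows = np.atleast_2d(current.data if isinstance(current, Tensor) else current).shape[0]
    if cur_rows != recorded.shape[0]:
        raise ValueError("recorded and current batches differ in size")
    penalty = distillation_ce(recorded, current, temperature)
    if isinstance(penalty, Tensor) or isinstance(new_task_loss, Tensor):
        return new_task_loss + lam * penalty
    return float(new_task_loss) + lam * penalty


# ---------------------------------------------------------------------------
# importance estimation (EWC Fisher, MAS Ω)
# ---------------------------------------------------------------------------

def empirical_fisher(apply_fn, params: list, inputs, labels) -> np.ndarray:
    """Diagonal empirical Fisher: mean over samples of (∂ log p(y|x)/∂θ_i)².

    ``apply_fn(sample) -> logits Tensor`` must route through ``params``.
    Ground-truth labels are used (not labels sampled from the model).
    """
    if len(inputs) == 0:
        raise ValueError("need at least one sample")
    total = np.zeros(sum(p.size for p in params))
    for x, y in zip(inputs, labels):
        logits = apply_fn(x)
        logp = ad.log_softmax(logits, axis=-1)
        ll = ad.sum_(ad.slice_axis(logp, int(y), int(y) + 1, axis=-1))
        gs = ad.grad(ll, params)
        flat = np.concatenate([g.data.ravel() for g in gs])
        total += flat ** 2
    return total / len(inputs)


def mas_importance(apply_fn, params: list, inputs) -> np.ndarray:
    """MAS importance: mean over samples of |∂ ‖M(x; θ)‖₂² / ∂θ_i|."""
    if len(inputs) == 0:
        raise ValueError("need at least one sample")
    total = np.zeros(sum(p.size for p in params))
    for x in inputs:
        out = apply_fn(x)
        norm2 = ad.sum_(out * out)
        gs = ad.grad(norm2, params)
        total += np.abs(np.concatenate([g.data.ravel() for g in gs]))
    return total / len(inputs)


def _detector_apply(model, record):
    from .model import demographics_matrix
    wave = Tensor(record.waveform[None])
    demo = Tensor(demographics_matrix([record]))
    return model(wave, demo)


def _sample_records(site_or_records, n_samples, seed):
    from .datasets import SiteDataset
    records = (site_or_records.subset("train")
               if isinstance(site_or_records, SiteDataset) and site_or_records.partitions
               else getattr(site_or_records, "records", site_or_records))
    if n_samples is not None:
        if n_samples == 0:
            raise ValueError("n_samples must be positive")
        if n_samples < len(records):
            rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF15]))
            idx = rng.choice(len(records), size=n_samples, replace=False)
            records = [records[i] for i in sorted(idx)]
    if not records:
        raise ValueError("no records to estimate importance from")
    return records


def estimate_fisher(model, site_or_records, n_samples: int | None = None,
                    seed: int = 0) -> np.ndarray:
    """Empirical Fisher of a trained detector over (a sample of) a train set."""
    records = _sample_records(site_or_records, n_samples, seed)
    was_training = model.training
    model.eval()  # per-sample batches: use running batch-norm statistics
    try:
        return empirical_fisher(lambda r: _detector_apply(model, r),
                                model.parameters(), records,
                                [r.label for r in records])
    finally:
        model.train(was_training)


def estimate_mas_importance(model, site_or_records, n_samples: int | None = None,
                            seed: int = 0) -> np.ndarray:
    """MAS importance of a trained detector over (a sample of) a train set."""
    records = _sample_records(site_or_records, n_samples, seed)
    was_training = model.training
    model.eval()
    try:
        return mas_importance(lambda r: _detector_apply(model, r),
                              model.parameters(), records)
    finally:
        model.train(was_training)


# ---------------------------------------------------------------------------
# quadratic penalties
# ---------------------------------------------------------------------------

def _quadratic_penalty(theta_new: np.ndarray, theta_old: np.ndarray,
                       weights: np.ndarray, lam: float) -> float:
    theta_new = np.asarray(theta_new, dtype=float)
    if theta_new.shape != theta_old.shape or weights.shape != theta_old.shape:
        raise ValueError("parameter index spaces do not match")
    return float(lam * np.sum(weights * (theta_new - theta_old) ** 2))


def ewc_penalty(theta_new, state: MethodState) -> float:
    """λ Σ_i F_i (θ_new,i − θ_old,i)²."""
    if state.fisher is None:
        raise ValueError("MethodState carries no Fisher weights")
    return _quadratic_penalty(theta_new, state.theta_old, state.fisher, state.lam)


def mas_penalty(theta_new, state: MethodState) -> float:
    """λ Σ_i Ω_i (θ_new,i − θ_old,i)²."""
    if state.omega is None:
        raise ValueError("MethodState carries no MAS weights")
    return _quadratic_penalty(theta_new, state.theta_old, state.omega, state.lam)


def penalty_gradient(theta_new: np.ndarray, state: MethodState) -> np.ndarray:
    """∂/∂θ of the active quadratic penalty: 2 λ w ⊙ (θ − θ_old).

    Used by the training loop to add the penalty analytically to the
    new-task gradient (the penalty is quadratic, so this is exact).
    """
    w = state.fisher if state.method_id == "EWC" else state.omega
    if w is None:
        raise ValueError(f"no importance weights for {state.method_id}")
    return 2.0 * state.lam * w * (np.asarray(theta_new) - state.theta_old)
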