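"""Training arms the continual framework is compared against.

* supervised — one site's data, or all sites merged, with the class-balanced
  cross-entropy;
* federated — FedAvg (size-weighted parameter averaging each round) and
  FedProx (FedAvg whose local objective adds the proximal term
  (μ/2)‖w_local − w_global‖²);
* finetuning — sequential training across sites with no regularization, the
  arm whose catastrophic forgetting the framework is meant to suppress.

All arms consume identical preprocessed :class:`~clms.datasets.SiteDataset`
objects and the same detector; only the training schedule differs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cl_methods import MethodState
from .datasets import SiteDataset
from .metrics import SiteMetric, weighted_auroc
from .model import Detector, DetectorConfig  # noqa: F401 (public surface)
from .nn import flatten_params, load_flat_params
from .training import (TrainResult, TrainSettings, balanced_ce_loss,
                       evaluate_auroc, train_detector)

__all__ = ["FederatedConfig", "balanced_ce_loss", "train_supervised",
           "fedavg_aggregate", "fedprox_local_loss", "run_federated",
           "run_finetuning", "merge_sites"]


@dataclass
class FederatedConfig:
    rounds: int = 30
    local_epochs: int = 20
    local_patience: int = 5
    mu: float = 0.01              # FedProx proximal coefficient
    lr: float = 1e-4
    batch_size: int = 256

    def __post_init__(self):
        if self.rounds < 1 or self.mu < 0:
            raise ValueError("rounds must be ≥ 1 and μ ≥ 0")

    @classmethod
    def tiny(cls) -> "FederatedConfig":
        return cls(rounds=3, local_epochs=6, local_patience=3, lr=3e-3, batch_size=32)


def merge_sites(sites: list[SiteDataset], site_id: str = "merged") -> SiteDataset:
    """Pool several split sites, preserving each record's partition."""
    records, parts = [], {"train": [], "val": [], "test": []}
    offset = 0
    for s in sites:
        s.validate_partitions()
        records.extend(s.records)
        for k in parts:
            parts[k].extend((np.asarray(s.partitions[k]) + offset).tolist())
        offset += s.size_n
    return SiteDataset(records, site_id, {k: np.array(v) for k, v in parts.items()})


def train_supervised(data: SiteDataset | list[SiteDataset],
                     detector_config: DetectorConfig,
                     settings: TrainSettings) -> TrainResult:
    """Supervised arm on one site or on merged sites."""
    site = merge_sites(data) if isinstance(data, list) else data
    model = Detector(detector_config)
    return train_detector(model, site, settings)


def fedavg_aggregate(client_params: list, client_sizes: list) -> np.ndarray:
    """Size-weighted average: w = Σ_k (n_k / n) w_k, element-wise."""
    if len(client_params) != len(client_sizes) or not client_params:
        raise ValueError("need matching nonempty parameter and size lists")
    shapes = {np.asarray(p).shape for p in client_params}
    if len(shapes) != 1:
        raise ValueError("client parameter index spaces do not match")
    sizes = np.asarray(client_sizes, dtype=float)
    if (sizes <= 0).any():
        raise ValueError("client sizes must be positive")
    weights = sizes / sizes.sum()
    return sum(w * np.asarray(p, dtype=float) for w, p in zip(weights, client_params))


def fedprox_local_loss(base_loss: float, w_local, w_global, mu: float) -> float:
    """base_loss + (μ/2)·‖w_local − w_global‖₂²."""
    w_local = np.asarray(w_local, dtype=float)
    w_global = np.asarray(w_global, dtype=float)
    if w_local.shape != w_global.shape:
        raise ValueError("parameter index spaces do not match")
    return float(base_loss) + 0.5 * mu * float(np.sum((w_local - w_global) ** 2))


def _proximal_state(w_global: np.ndarray, mu: float) -> MethodState:
    # the proximal term is the EWC-form quadratic with unit weights, λ = μ/2
    return MethodState(method_id="EWC", theta_old=w_global.copy(), lam=mu / 2.0,
                       fisher=np.ones_like(w_global))


def run_federated(sites: list[SiteDataset], config: FederatedConfig,
                  detector_config: DetectorConfig, algorithm: str = "fedavg",
                  seed: int = 0):
    """FedAvg / FedProx over ``config.rounds``; keeps the round checkpoint with
    the best weighted-average validation AUROC across sites."""
    if algorithm not in ("fedavg", "fedprox"):
        raise ValueError(f"unknown federated algorithm {algorithm!r}")
    if not sites:
        raise ValueError("need at least one site")
    model = Detector(detector_config)
    global_state = model.state_dict()
    best_metric, best_state = -np.inf, dict(global_state)
    metrics_log = []
    for rnd in range(config.rounds):
        client_states, client_sizes, round_metrics = [], [], []
        for si, site in enumerate(sites):
            model.load_state_dict(global_state)
            settings = TrainSettings(epochs=config.local_epochs,
                                     patience=config.local_patience,
                                     lr=config.lr, batch_size=config.batch_size,
                                     seed=int(np.random.default_rng(
                                         np.random.SeedSequence([seed, rnd, si])
                                     ).integers(2 ** 31)))
            state = (_proximal_state(flatten_params(model), config.mu)
                     if algorithm == "fedprox" and config.mu > 0 else None)
            res = train_detector(model, site, settings, method_state=state)
            client_states.append(res.state)
            client_sizes.append(len(site.subset("train")))
            round_metrics.append(SiteMetric(site.site_id, site.size_n,
                                            res.best_val_metric))
            metrics_log.append({"round": rnd, "site": site.site_id,
                                "val_auroc": res.best_val_metric})
        # size-weighted average of every named group (batch-norm stats included)
        global_state = {k: fedavg_aggregate([cs[k] for cs in client_states],
                                            client_sizes)
                        for k in client_states[0]}
        model.load_state_dict(global_state)
        agg_metrics = [SiteMetric(s.site_id, s.size_n,
                                  evaluate_auroc(model, s.subset("val")))
                       for s in sites]
        wavg = weighted_auroc(agg_metrics)
        metrics_log.append({"round": rnd, "site": "__aggregate__", "val_auroc": wavg})
        if wavg > best_metric:
            best_metric = wavg
            best_state = {k: v.copy() for k, v in global_state.items()}
    return best_state, metrics_log


def run_finetuning(sites: list[SiteDataset], detector_config: DetectorConfig,
                   settings: TrainSettings, seed: int = 0):
    """Sequential finetuning across ≥ 2 ordered sites; no regularization.

    Returns the final parameters and the stages × sites validation-AUROC
    matrix (every site evaluated after every stage — the forgetting
    trajectory).
    """
    if len(sites) < 2:
        raise ValueError("finetuning needs at least 2 sites")
    model = Detector(detector_config)
    stage_metrics = []
    state = model.state_dict()
    for k, site in enumerate(sites):
        model.load_state_dict(state)
        stage_settings = TrainSettings(epochs=settings.epochs, patience=settings.patience,
                                       lr=settings.lr, batch_size=settings.batch_size,
                                       seed=int(np.random.default_rng(
                                           np.random.SeedSequence([seed, 0xF7, k])
                                       ).integers(2 ** 31)))
        res = train_detector(model, site, stage_settings)
        state = res.state
        model.load_state_dict(state)
        stage_metrics.append([evaluate_auroc(model, s.subset("val")) for s in sites])
    return state, np.array(stage_metrics)
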