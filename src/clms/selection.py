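"""Continual-learning method selection and the multicenter driver.

At each institution k ≥ 2 the framework runs three steps:

1. **Finetune baseline** — the incoming model θ*_{k−1} is finetuned on the
   site's data with no regularization, yielding the baseline validation AUROC
   p* and model hyperparameters h*.
2. **Candidate training with hyperparameter decay** — each candidate method
   (LwF, EWC, MAS) trains from θ*_{k−1} with its regularizer at λ = λ_init
   (maximal stability).  If the resulting validation AUROC falls below the
   reference threshold the method retrains from θ*_{k−1} with λ ← α·λ,
   repeating until the threshold is met or ``max_decay_steps`` is exhausted.
   Two threshold readings are supported: ``drop_margin`` ((1−δ)·p*, the
   literal formula, which with δ = 0.95 is a very permissive 5% of baseline)
   and ``fraction_retained`` (δ·p*, requiring 95% of baseline to be
   retained); the default follows the literal formula.
3. **Fake-data evaluation** — every candidate's parameters are scored by
   weighted-average AUROC over the accumulated fake datasets from previous
   sites, and the best-scoring candidate's parameters become θ*_k.

Between institutions only θ*_k, the method state (θ_old, importances, frozen
old model), the synthesizer state, and the accumulated fake data are handed
off — never raw records.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .cl_methods import (METHODS, MethodState, estimate_fisher,
                         estimate_mas_importance)
from .datasets import SiteDataset
from .generative import (FakeDataset, SynthConfig, SynthesizerState,
                         demographics_pool_of, fake_group_sizes,
                         generate_fake_dataset, train_synthesizer)
from .metrics import SiteMetric, auroc, weighted_auroc
from .model import Detector, DetectorConfig, demographics_matrix, predict_proba, waveform_batch
from .nn import flatten_params, load_flat_params
from .training import TrainResult, TrainSettings, train_detector

__all__ = ["SelectionConfig", "SelectionHistory", "finetune_baseline",
           "train_with_method", "evaluate_on_fake", "select_method",
           "order_sites", "run_multicenter", "Handoff"]


@dataclass
class SelectionConfig:
    candidates: tuple = METHODS
    lambda_init: float = 1.0
    temperature: float = 10.0
    alpha: float = 0.9            # decay factor for λ
    delta: float = 0.95           # performance drop margin
    reference_mode: str = "drop_margin"   # or "fraction_retained"
    max_decay_steps: int = 20
    importance_accumulation: str = "replace"  # or "sum"
    n_fake_cap: int = 2000
    train_settings: TrainSettings = field(default_factory=TrainSettings)

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("α must lie in (0, 1)")
        if not 0 <= self.delta <= 1:
            raise ValueError("δ must lie in [0, 1]")
        if self.max_decay_steps < 1:
            raise ValueError("max_decay_steps must be ≥ 1")
        if self.reference_mode not in ("drop_margin", "fraction_retained"):
            raise ValueError(f"unknown reference_mode {self.reference_mode!r}")

    def threshold(self, p_star: float) -> float:
        if self.reference_mode == "drop_margin":
            return (1.0 - self.delta) * p_star
        return self.delta * p_star

    @classmethod
    def tiny(cls, seed: int = 0) -> "SelectionConfig":
        return cls(max_decay_steps=5, n_fake_cap=96,
                   train_settings=TrainSettings.tiny(seed=seed))


@dataclass
class SelectionHistory:
    entries: list = field(default_factory=list)
    stage_states: list = field(default_factory=list)  # per-stage selected model states

    def add(self, site_id, fake_scores: dict, chosen: str, lambdas: dict,
            p_star: float):
        best = max(fake_scores.values())
        if fake_scores[chosen] != best:
            raise ValueError("chosen method must attain the maximal fake score")
        self.entries.append({"site_id": site_id, "fake_scores": dict(fake_scores),
                             "chosen": chosen, "lambdas": dict(lambdas),
                             "p_star": p_star})


# ---------------------------------------------------------------------------
# Algorithm steps
# ---------------------------------------------------------------------------

def _load_theta(model: Detector, theta):
    """Accept either a full state dict (named groups + buffers) or a flat θ."""
    if isinstance(theta, dict):
        model.load_state_dict(theta)
    else:
        load_flat_params(model, theta)


def finetune_baseline(theta_prev, site: SiteDataset,
                      config: SelectionConfig,
                      detector_config: DetectorConfig) -> TrainResult:
    """Step 1: finetune the previous model with no regularization → p*, h*."""
    model = Detector(detector_config)
    _load_theta(model, theta_prev)
    return train_detector(model, site, config.train_settings)


def train_with_method(theta_prev, site: SiteDataset, method_id: str,
                      prev_state: MethodState, p_star: float,
                      config: SelectionConfig,
                      detector_config: DetectorConfig,
                      threshold: float | None = None):
    """Step 2: candidate training with geometric λ decay.

    Each attempt restarts from ``theta_prev`` with λ = λ_init·αʲ; stops at the
    first attempt whose validation AUROC meets the reference threshold, or
    returns the best attempt so far after ``max_decay_steps`` (decay trace
    flagged as exhausted).  Returns (TrainResult, updated MethodState).
    """
    if method_id not in METHODS:
        raise ValueError(f"unknown method {method_id!r}")
    if threshold is None:
        threshold = config.threshold(p_star)
    decay_trace = []
    best: TrainResult | None = None
    best_lam = config.lambda_init
    for step in range(config.max_decay_steps):
        lam = config.lambda_init * config.alpha ** step
        state = replace(prev_state, method_id=method_id, lam=lam,
                        temperature=config.temperature)
        model = Detector(detector_config)
        _load_theta(model, theta_prev)
        res = train_detector(model, site, config.train_settings, method_state=state)
        decay_trace.append((lam, res.best_val_metric))
        if best is None or res.best_val_metric > best.best_val_metric:
            best, best_lam = res, lam
        if res.best_val_metric >= threshold:
            best, best_lam = res, lam
            break
    else:
        best.hyperparams["decay_exhausted"] = True
    best.decay_trace = decay_trace
    best.hyperparams["lambda"] = best_lam

    # re-estimate importances on the current site with the trained parameters
    model = Detector(detector_config)
    model.load_state_dict(best.state)
    new_state = _handoff_method_state(model, site, config,
                                      prev_state=prev_state, lam=best_lam)
    return best, new_state


def _handoff_method_state(model: Detector, site: SiteDataset,
                          config: SelectionConfig,
                          prev_state: MethodState | None = None,
                          lam: float | None = None,
                          n_importance: int | None = 64) -> MethodState:
    """Estimate both importances with the (loaded) model on this site's data."""
    theta = flatten_params(model)
    fisher = estimate_fisher(model, site, n_samples=n_importance,
                             seed=config.train_settings.seed)
    omega = estimate_mas_importance(model, site, n_samples=n_importance,
                                    seed=config.train_settings.seed)
    if config.importance_accumulation == "sum" and prev_state is not None:
        if prev_state.fisher is not None:
            fisher = fisher + prev_state.fisher
        if prev_state.omega is not None:
            omega = omega + prev_state.omega
    return MethodState(method_id="EWC", theta_old=theta.copy(),
                       lam=lam if lam is not None else config.lambda_init,
                       temperature=config.temperature, fisher=fisher, omega=omega,
                       old_model_state=model.state_dict())


def evaluate_on_fake(params, fake_sets: list[FakeDataset],
                     detector_config: DetectorConfig) -> float:
    """Step 3: weighted-average AUROC over accumulated fake sets (weights =
    set sizes); single-class sets are skipped with a warning."""
    if not fake_sets:
        raise ValueError("need at least one fake dataset")
    model = Detector(detector_config)
    _load_theta(model, params)
    model.eval()
    metrics = []
    for fs in fake_sets:
        labels = [r.label for r in fs.records]
        if len(set(labels)) < 2:
            warnings.warn(f"fake set from {fs.source_site} has a single class; skipped")
            continue
        probs = predict_proba(model, waveform_batch(fs.records),
                              demographics_matrix(fs.records))
        metrics.append(SiteMetric(fs.source_site, fs.size,
                                  auroc(probs[:, 1], labels)))
    if not metrics:
        raise ValueError("all fake sets were single-class; cannot evaluate")
    return weighted_auroc(metrics)


def select_method(results: dict, candidate_order=METHODS):
    """Argmax of the fake score; exact ties go to the earlier candidate."""
    if not results:
        raise ValueError("no candidate results")
    ordered = [m for m in candidate_order if m in results]
    best = max(ordered, key=lambda m: results[m][1])
    return best, results[best][0].params


def order_sites(sites: list[SiteDataset], order: str) -> list[SiteDataset]:
    """Sort sites by size (ties broken by site_id, lexicographic)."""
    if order not in ("small_to_large", "large_to_small"):
        raise ValueError(f"unknown order {order!r}")
    key = lambda s: (s.size_n, s.site_id)
    out = sorted(sites, key=key)
    return out[::-1] if order == "large_to_small" else out


# ---------------------------------------------------------------------------
# multicenter driver
# ---------------------------------------------------------------------------

@dataclass
class Handoff:
    """Everything allowed to move between institutions — never raw records."""

    theta_star: dict  # the selected model's named parameter groups (+ buffers)
    method_state: MethodState
    synth_state: SynthesizerState
    fake_sets: list[FakeDataset]

    ALLOWED_FIELDS = ("theta_star", "method_state", "synth_state", "fake_sets")

    def assert_no_raw_records(self, real_sites: list[SiteDataset]):
        """Structural privacy check: no real record id or waveform crosses."""
        real_ids = {r.record_id for s in real_sites for r in s.records}
        real_hashes = {hashlib.sha1(np.ascontiguousarray(r.waveform).tobytes()).hexdigest()
                       for s in real_sites for r in s.records}
        for fs in self.fake_sets:
            for r in fs.records:
                if r.record_id in real_ids:
                    raise AssertionError(f"fake record id {r.record_id} aliases a real record")
                h = hashlib.sha1(np.ascontiguousarray(r.waveform).tobytes()).hexdigest()
                if h in real_hashes:
                    raise AssertionError("a fake waveform is bit-identical to a real record")
        extra = set(self.__dict__) - set(self.ALLOWED_FIELDS)
        if extra:
            raise AssertionError(f"hand-off carries disallowed fields: {extra}")

    def save(self, directory):
        from pathlib import Path
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(directory / "theta_star.npz", **self.theta_star)
        ms = self.method_state
        np.savez_compressed(directory / "method_state.npz",
                            theta_old=ms.theta_old, fisher=ms.fisher, omega=ms.omega,
                            lam=np.array([ms.lam]), temperature=np.array([ms.temperature]),
                            **{f"old__{k}": v for k, v in (ms.old_model_state or {}).items()})
        for label, sd in self.synth_state.generators.items():
            np.savez_compressed(directory / f"synth_gen_{label}.npz", **sd)
            np.savez_compressed(directory / f"synth_critic_{label}.npz",
                                **self.synth_state.critics[label])
        for i, fs in enumerate(self.fake_sets):
            sd = SiteDataset(fs.records, f"fake:{fs.source_site}")
            sd.save_npz(directory / f"fake_{i}.npz")
        manifest = {"files": {}, "synthetic": True}
        for f in sorted(directory.glob("*.npz")):
            manifest["files"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def _fake_counts(site: SiteDataset, cap: int) -> dict:
    train = site.subset("train")
    counts = {0: sum(r.label == 0 for r in train), 1: sum(r.label == 1 for r in train)}
    n_fake = min(len(train), cap)
    return fake_group_sizes(counts, n_fake)


def run_multicenter(sites: list[SiteDataset], config: SelectionConfig,
                    synth_config: SynthConfig,
                    detector_config: DetectorConfig, seed: int = 0,
                    check_privacy: bool = True,
                    keep_stage_states: bool = False):
    """Chain the framework across ≥ 2 ordered sites.

    Site 1 trains plainly (nothing to preserve) and seeds the synthesizer;
    every later site runs the three-step selection against the accumulated
    fake data, then trains its own synthesizer (warm-started) and appends its
    fake dataset to the hand-off.
    """
    if len(sites) < 2:
        raise ValueError("a multicenter run needs at least 2 sites")
    history = SelectionHistory()

    # --- site 1: plain supervised training, synthesizer, first fake set ----
    first = sites[0]
    model = Detector(detector_config)
    res = train_detector(model, first, config.train_settings)
    theta = res.state
    synth_state = train_synthesizer(first, synth_config, init=None, seed=seed)
    fake = generate_fake_dataset(synth_state, demographics_pool_of(first.subset("train")),
                                 _fake_counts(first, config.n_fake_cap), seed=seed)
    method_state = _handoff_method_state(model, first, config)
    handoff = Handoff(theta, method_state, synth_state, [fake])
    if keep_stage_states:
        history.stage_states.append(theta)
    if check_privacy:
        handoff.assert_no_raw_records(sites)

    # --- sites k >= 2: Algorithm 1 ----------------------------------------
    for k, site in enumerate(sites[1:], start=2):
        base = finetune_baseline(handoff.theta_star, site, config, detector_config)
        results, lambdas = {}, {}
        for method_id in config.candidates:
            cand, cand_state = train_with_method(
                handoff.theta_star, site, method_id, handoff.method_state,
                base.best_val_metric, config, detector_config)
            score = evaluate_on_fake(cand.state, handoff.fake_sets, detector_config)
            results[method_id] = (cand, score, cand_state)
            lambdas[method_id] = cand.hyperparams["lambda"]
        chosen, _ = select_method(
            {m: (r[0], r[1]) for m, r in results.items()}, config.candidates)
        theta = results[chosen][0].state
        history.add(site.site_id, {m: r[1] for m, r in results.items()},
                    chosen, lambdas, base.best_val_metric)

        synth_state = train_synthesizer(site, synth_config, init=handoff.synth_state,
                                        seed=seed + k)
        fake = generate_fake_dataset(synth_state,
                                     demographics_pool_of(site.subset("train")),
                                     _fake_counts(site, config.n_fake_cap), seed=seed + k)
        method_state = results[chosen][2]
        handoff = Handoff(theta, method_state, synth_state,
                          handoff.fake_sets + [fake])
        if keep_stage_states:
            history.stage_states.append(theta)
        if check_privacy:
            handoff.assert_no_raw_records(sites)

    return handoff.theta_star, history
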