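"""Desk-scale simulator of heterogeneous multicenter 12-lead ECG-like data.

Each record is a sum of lead-projected Gaussian P-QRS-T beat templates placed
at RR-jittered beat times, plus sinusoidal baseline wander and white noise,
with per-site lead gains.  Arrhythmia (label 1) is encoded as RR-interval
irregularity plus P-wave dropout — a deliberate caricature that gives a
detector a learnable rhythm signal without any claim of clinical realism.
Site profiles control cohort heterogeneity (age and sex distribution,
arrhythmia prevalence) and device/regional morphology shift, emulating the
kind of between-institution variation seen across public ECG databases.

All sampling is deterministic given the integer seed: every operation derives
its own ``numpy`` generator from ``SeedSequence([seed, tag])``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import ECGRecord, FEMALE, MALE, SiteDataset


@dataclass
class SiteProfile:
    """Cohort + acquisition characteristics of one simulated institution."""

    n: int = 100
    age_mean: float = 60.0
    age_sd: float = 16.0
    male_fraction: float = 0.45
    arrhythmia_prevalence: float = 0.6
    lead_gains: np.ndarray | None = None   # per-lead multipliers (device shift)
    wander_amp: float = 0.05               # mV, baseline wander
    noise_sd: float = 0.02                 # mV, white noise
    rr_cv_normal: float = 0.03
    rr_cv_arrhythmia: float = 0.25
    p_wave_dropout: float = 0.7            # P(beat loses its P wave | label 1)
    male_prevalence: float | None = None   # sex-conditional prevalence override
    female_prevalence: float | None = None
    site_id: str = "site"

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for p in (self.male_fraction, self.arrhythmia_prevalence, self.p_wave_dropout,
                  self.male_prevalence, self.female_prevalence):
            if p is not None and not 0.0 <= p <= 1.0:
                raise ValueError("proportions must lie in [0, 1]")
        if not self.rr_cv_arrhythmia > self.rr_cv_normal:
            raise ValueError("rr_cv_arrhythmia must exceed rr_cv_normal")


@dataclass
class SimConfig:
    """Waveform-shape parameters shared by all sites of a scenario."""

    leads: int = 12
    fs: float = 500.0
    duration: float = 10.0
    rr_mean: float = 0.8        # s, mean beat-to-beat interval
    p_amp: float = 0.15
    p_width: float = 0.025      # s
    p_offset: float = -0.16     # s relative to R peak
    q_amp: float = -0.1
    r_amp: float = 1.0
    qrs_width: float = 0.012
    s_amp: float = -0.25
    t_amp: float = 0.3
    t_width: float = 0.06
    t_offset: float = 0.24
    projections: np.ndarray | None = None  # (3, leads): P/QRS/T lead weights
    seed: int = 0

    @property
    def n_samples(self) -> int:
        n = self.fs * self.duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs × duration must be integral")
        return int(round(n))

    def lead_projections(self) -> np.ndarray:
        if self.projections is not None:
            return np.asarray(self.projections, dtype=float)
        # fixed plausible lead weights: smooth variation across the 12 leads
        k = np.arange(self.leads)
        p = 0.6 + 0.4 * np.cos(2 * np.pi * k / self.leads)
        qrs = np.where(k < self.leads // 2, 1.0 - 0.08 * k, 0.4 + 0.1 * (k - self.leads // 2))
        t = 0.8 + 0.2 * np.sin(2 * np.pi * k / self.leads)
        return np.stack([p, qrs, t])


def _gauss(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def simulate_record(profile: SiteProfile, config: SimConfig, label: int,
                    seed: int, sex: str | None = None,
                    age: int | None = None) -> ECGRecord:
    """Generate one labeled record; fully deterministic under ``seed``.

    ``sex``/``age`` may be pre-drawn by the caller (used when labels are
    conditioned on demographics); otherwise they are sampled here.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xEC6]))
    n = config.n_samples
    t = np.arange(n) / config.fs
    cv = profile.rr_cv_arrhythmia if label == 1 else profile.rr_cv_normal

    # beat times with multiplicative RR jitter
    beats = []
    pos = 0.3 * config.rr_mean
    while pos < config.duration + config.rr_mean:
        beats.append(pos)
        rr = config.rr_mean * max(0.3, 1.0 + cv * rng.standard_normal())
        pos += rr

    proj = config.lead_projections()
    base = np.zeros((3, n))  # P, QRS, T components before lead projection
    for b in beats:
        if label == 1 and rng.random() < profile.p_wave_dropout:
            p_here = 0.0
        else:
            p_here = config.p_amp
        base[0] += p_here * _gauss(t, b + config.p_offset, config.p_width)
        base[1] += (config.q_amp * _gauss(t, b - 2.5 * config.qrs_width, config.qrs_width)
                    + config.r_amp * _gauss(t, b, config.qrs_width)
                    + config.s_amp * _gauss(t, b + 2.5 * config.qrs_width, config.qrs_width))
        base[2] += config.t_amp * _gauss(t, b + config.t_offset, config.t_width)

    wave = proj.T @ base  # (leads, n)
    if profile.wander_amp > 0:
        f = rng.uniform(0.15, 0.4)
        phase = rng.uniform(0, 2 * np.pi, size=(config.leads, 1))
        wave = wave + profile.wander_amp * np.sin(2 * np.pi * f * t[None, :] + phase)
    if profile.noise_sd > 0:
        wave = wave + rng.normal(0, profile.noise_sd, size=wave.shape)
    gains = (np.ones(config.leads) if profile.lead_gains is None
             else np.asarray(profile.lead_gains, dtype=float))
    wave = wave * gains[:, None]

    if age is None:
        age = int(np.clip(round(rng.normal(profile.age_mean, profile.age_sd)), 18, 100))
    if sex is None:
        sex = MALE if rng.random() < profile.male_fraction else FEMALE
    return ECGRecord(wave, config.fs, age, sex, int(label),
                     record_id=f"{profile.site_id}-r{seed}", site_id=profile.site_id)


def simulate_site(profile: SiteProfile, config: SimConfig, seed: int) -> SiteDataset:
    """Generate a full site; labels ~ Bernoulli(arrhythmia_prevalence).

    When the profile sets sex-conditional prevalences, sex is drawn first and
    the label follows Bernoulli(prevalence | sex) — the site-level analogue of
    cohorts whose arrhythmia burden differs between demographic strata.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x517E]))
    sexes = np.where(rng.random(profile.n) < profile.male_fraction, MALE, FEMALE)
    prev = np.full(profile.n, profile.arrhythmia_prevalence)
    if profile.male_prevalence is not None:
        prev[sexes == MALE] = profile.male_prevalence
    if profile.female_prevalence is not None:
        prev[sexes == FEMALE] = profile.female_prevalence
    labels = (rng.random(profile.n) < prev).astype(int)
    rec_seeds = rng.integers(0, 2 ** 31 - 1, size=profile.n)
    records = []
    for i in range(profile.n):
        r = simulate_record(profile, config, int(labels[i]), int(rec_seeds[i]),
                            sex=str(sexes[i]))
        r.record_id = f"{profile.site_id}-{i:05d}"
        records.append(r)
    return SiteDataset(records, profile.site_id)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def _site_gains(leads: int, site_idx: int, strength: float = 0.15) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([0x6A15, site_idx]))
    return 1.0 + strength * rng.standard_normal(leads)


def default_multicenter_scenario(scale: str = "tiny"):
    """Four heterogeneous site profiles mirroring a multi-database setting.

    Sites have pairwise-distinct sizes (so size orderings differ), distinct
    arrhythmia prevalences with one low-prevalence outlier, and distinct
    device morphology (lead gains, wander, noise).  ``tiny`` runs end-to-end
    in minutes on one CPU; ``paper-like`` uses the printed cohort sizes and
    prevalences of the four public databases.
    """
    if scale == "tiny":
        ns = [80, 96, 112, 128]
        config = SimConfig(fs=125.0, duration=2.4)
    elif scale == "small":
        ns = [150, 200, 260, 320]
        config = SimConfig(fs=125.0, duration=2.4)
    elif scale in ("paper-like", "paper"):
        ns = [21374, 10197, 6696, 4032]
        config = SimConfig(fs=500.0, duration=10.0)
    else:
        raise ValueError(f"unknown scale {scale!r}")

    prevalences = [0.5612, 0.8201, 0.8321, 0.8775]  # one low-prevalence outlier
    age_stats = [(60.79, 16.41), (59.82, 16.42), (60.54, 15.4), (61.18, 17.9)]
    male_fracs = [0.4361, 0.4750, 0.4631, 0.4618]
    wander = [0.03, 0.08, 0.05, 0.12]
    noise = [0.015, 0.04, 0.025, 0.06]
    profiles = []
    for i in range(4):
        profiles.append(SiteProfile(
            n=ns[i], age_mean=age_stats[i][0], age_sd=age_stats[i][1],
            male_fraction=male_fracs[i], arrhythmia_prevalence=prevalences[i],
            lead_gains=_site_gains(config.leads, i),
            wander_amp=wander[i], noise_sd=noise[i],
            rr_cv_normal=0.03, rr_cv_arrhythmia=0.25,
            site_id=f"site{i + 1}"))
    return [(p, config) for p in profiles]


def strong_shift_scenario(n_sites: int = 3, n_per_site: int = 160):
    """Small multi-site scenario with deliberately strong domain shift.

    Later sites flip and rescale lead polarities, carry heavier wander and
    noise, and reverse the association between sex and arrhythmia prevalence
    (site 1: predominantly male arrhythmia; site 3: predominantly female),
    so sequential finetuning across sites exhibits measurable catastrophic
    forgetting on site 1.
    """
    config = SimConfig(fs=125.0, duration=2.4)
    profiles = []
    cv_pairs = [(0.04, 0.25), (0.06, 0.22), (0.08, 0.30)]
    sex_prev = [(0.9, 0.1), (0.5, 0.5), (0.05, 0.95)]  # (male, female) P(arrhythmia)
    for i in range(n_sites):
        gains = _site_gains(config.leads, 100 + i, strength=0.1)
        if i > 0:  # flip polarity of a growing subset of leads
            flip = np.arange(config.leads) % (i + 1) == 0
            gains = np.where(flip, -1.4 * gains, 0.6 * gains)
        mp, fp = sex_prev[i % len(sex_prev)]
        profiles.append(SiteProfile(
            n=n_per_site + 8 * i, age_mean=50 + 8 * i, age_sd=12.0,
            male_fraction=0.5, arrhythmia_prevalence=0.5,
            male_prevalence=mp, female_prevalence=fp,
            lead_gains=gains, wander_amp=0.02 + 0.05 * i,
            noise_sd=0.03 + 0.03 * i,
            rr_cv_normal=cv_pairs[i % len(cv_pairs)][0],
            rr_cv_arrhythmia=cv_pairs[i % len(cv_pairs)][1],
            site_id=f"site{i + 1}"))
    return [(p, config) for p in profiles]


def simulate_scenario(scenario, seed: int = 0) -> list[SiteDataset]:
    """Instantiate every site of a scenario with per-site derived seeds."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5CEA]))
    site_seeds = rng.integers(0, 2 ** 31 - 1, size=len(scenario))
    return [simulate_site(p, c, int(s)) for (p, c), s in zip(scenario, site_seeds)]
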