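"""WGAN-GP waveform synthesizer and privacy-oriented fake-data construction.

A WaveGAN-style 1-D Wasserstein GAN with gradient penalty: the generator maps
a latent vector through a dense projection and repeated (nearest-neighbour
upsample → convolution) stages to a 12-channel waveform; the critic is a
strided convolutional stack with phase shuffle (small random circular shifts
of activations, so the generator cannot exploit trivial periodic phase cues)
ending in a dense scalar.  Channel widths, depths and lengths are fully
configurable so tiny variants train on one CPU.

Training follows the standard WGAN-GP recipe: five critic updates per
generator update, gradient-penalty weight 10, early stopping when the
per-epoch mean negative critic loss stops decreasing.  One synthesizer is
trained per label group (with / without arrhythmia); a site's synthesizer can
warm-start from the previous site's parameters.

Fake records pair synthesized waveforms with (age, sex) pairs drawn jointly
(with replacement) from the source group's real demographic pool: the joint
age-sex distribution is preserved, but the waveform-demographics linkage is
random and never derived from any real record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad, nn
from .autodiff import Tensor
from .datasets import ECGRecord, FEMALE, MALE, SiteDataset


@dataclass
class SynthConfig:
    leads: int = 12
    out_len: int = 5000
    fs: float = 500.0
    latent_dim: int = 64
    gen_channels: tuple = (64, 32)       # one conv per ×2 upsample stage
    critic_channels: tuple = (32, 64)
    critic_stride: int = 5
    kernel: int = 9
    phase_shuffle: int = 2
    lr: float = 1e-4
    betas: tuple = (0.5, 0.9)
    batch_size: int = 64
    critic_steps: int = 5
    gp_weight: float = 10.0
    epochs: int = 2000
    patience: int = 100
    per_epoch_alternation: bool = False  # alternative reading of the 5:1 ratio
    seed: int = 0

    @classmethod
    def paper_scale(cls, **kw) -> "SynthConfig":
        return cls(**kw)

    @classmethod
    def tiny(cls, out_len: int = 300, leads: int = 12, seed: int = 0) -> "SynthConfig":
        return cls(leads=leads, out_len=out_len, fs=125.0, latent_dim=32,
                   gen_channels=(24, 16), critic_channels=(16, 24),
                   lr=1e-3, batch_size=16, epochs=12, patience=6, seed=seed)


class Generator(nn.Module):
    def __init__(self, config: SynthConfig, rng):
        super().__init__()
        self.config = config
        n_up = len(config.gen_channels)
        if config.out_len % (2 ** n_up):
            raise ValueError("out_len must be divisible by 2^(number of stages)")
        self.l0 = config.out_len // (2 ** n_up)
        c0 = config.gen_channels[0]
        self.project = nn.Linear(config.latent_dim, c0 * self.l0, rng=rng)
        chans = list(config.gen_channels) + [config.leads]
        for i in range(n_up):
            setattr(self, f"conv{i}", nn.Conv1d(chans[i], chans[i + 1],
                                                config.kernel, rng=rng))
        self.n_up = n_up
        self.c0 = c0

    def forward(self, z: Tensor) -> Tensor:
        h = ad.relu(self.project(z))
        h = ad.reshape(h, (z.shape[0], self.c0, self.l0))
        for i in range(self.n_up):
            n, c, ln = h.shape
            h = ad.reshape(ad.broadcast_to(ad.reshape(h, (n, c, ln, 1)),
                                           (n, c, ln, 2)), (n, c, 2 * ln))
            h = getattr(self, f"conv{i}")(h)
            if i < self.n_up - 1:
                h = ad.relu(h)
        return ad.tanh(h)


class Critic(nn.Module):
    def __init__(self, config: SynthConfig, rng):
        super().__init__()
        self.config = config
        chans = [config.leads] + list(config.critic_channels)
        length = config.out_len
        for i in range(len(config.critic_channels)):
            setattr(self, f"conv{i}", nn.Conv1d(chans[i], chans[i + 1], config.kernel,
                                                stride=config.critic_stride, rng=rng))
            length = -(-length // config.critic_stride)
        self.n_conv = len(config.critic_channels)
        self.out = nn.Linear(chans[-1] * length, 1, rng=rng)
        self._shuffle_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 0x5face]))

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for i in range(self.n_conv):
            h = ad.leaky_relu(getattr(self, f"conv{i}")(h), 0.2)
            k = self.config.phase_shuffle
            if k > 0 and self.training:
                shift = int(self._shuffle_rng.integers(-k, k + 1))
                if shift:
                    h = ad.roll_last(h, shift)
        h = ad.reshape(h, (h.shape[0], -1))
        return ad.reshape(self.out(h), (-1,))


@dataclass
class SynthesizerState:
    """Per-label-group generator/critic parameters, transferable between sites."""

    config: SynthConfig
    generators: dict = field(default_factory=dict)   # label -> state_dict
    critics: dict = field(default_factory=dict)
    site_chain: list = field(default_factory=list)   # provenance
    training_log: dict = field(default_factory=dict)

    def build_generator(self, label: int) -> Generator:
        g = Generator(self.config, np.random.default_rng(0))
        g.load_state_dict(self.generators[label])
        return g


# ---------------------------------------------------------------------------
# WGAN-GP losses
# ---------------------------------------------------------------------------

def gradient_penalty(critic, real_batch, fake_batch, seed: int = 0):
    """Mean over interpolates x̂ = εx_real + (1−ε)x_fake of (‖∇_x̂ D(x̂)‖₂ − 1)².

    Returns a Tensor (graph-carrying, so the penalty can be differentiated
    with respect to the critic's parameters); use ``.item()`` for the value.
    """
    real = real_batch.data if isinstance(real_batch, Tensor) else np.asarray(real_batch, float)
    fake = fake_batch.data if isinstance(fake_batch, Tensor) else np.asarray(fake_batch, float)
    if real.shape != fake.shape:
        raise ValueError("real and fake batches must share a shape")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x69b]))
    eps = rng.uniform(0, 1, size=(real.shape[0],) + (1,) * (real.ndim - 1))
    xhat = Tensor(eps * real + (1 - eps) * fake, requires_grad=True)
    out = critic(xhat)
    (gx,) = ad.grad(ad.sum_(out), [xhat], create_graph=True)
    axes = tuple(range(1, real.ndim))
    norms = ad.sqrt(ad.sum_(gx * gx, axis=axes) + Tensor(1e-12))
    return ad.mean_((norms - Tensor(1.0)) ** 2)


def wgan_gp_losses(critic_real, critic_fake, gp, gp_weight: float = 10.0):
    """(critic_loss, generator_loss) from critic scores and the penalty.

    critic_loss = mean(D(fake)) − mean(D(real)) + gp_weight·gp;
    generator_loss = −mean(D(fake)).
    """
    def _mean(v):
        return ad.mean_(v) if isinstance(v, Tensor) else float(np.mean(v))

    mr, mf = _mean(critic_real), _mean(critic_fake)
    tensor_mode = any(isinstance(v, Tensor) for v in (mr, mf, gp))
    critic_loss = mf - mr + gp_weight * gp
    gen_loss = -mf if isinstance(mf, Tensor) else -float(mf)
    if not tensor_mode:
        critic_loss = float(critic_loss)
    return critic_loss, gen_loss


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _real_matrix(records) -> np.ndarray:
    return np.stack([r.waveform for r in records])


def train_synthesizer(site: SiteDataset, config: SynthConfig | None = None,
                      init: SynthesizerState | None = None,
                      seed: int = 0) -> SynthesizerState:
    """Train one generator/critic pair per label group on site.train.

    ``init`` warm-starts both networks from a previous site's state.  The
    training log records every update, so the 5:1 critic/generator ratio is
    auditable.
    """
    config = config or SynthConfig()
    train_recs = site.subset("train") if site.partitions else site.records
    state = SynthesizerState(config=config,
                             site_chain=(list(init.site_chain) if init else []) + [site.site_id])

    for label in (0, 1):
        group = [r for r in train_recs if r.label == label]
        if not group:
            raise ValueError(f"label group {label} is empty at site {site.site_id!r}")
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6A0 + label]))
        gen = Generator(config, rng)
        critic = Critic(config, rng)
        if init is not None:
            gen.load_state_dict(init.generators[label])
            critic.load_state_dict(init.critics[label])
        g_opt = nn.Adam(gen.parameters(), lr=config.lr, betas=config.betas)
        c_opt = nn.Adam(critic.parameters(), lr=config.lr, betas=config.betas)
        real = _real_matrix(group)
        log = {"critic_updates": 0, "gen_updates": 0, "neg_critic_loss": []}
        best_ncl, best_epoch = np.inf, 0

        for epoch in range(config.epochs):
            epoch_ncl = []
            n_batches = max(1, len(group) // config.batch_size)
            for _ in range(n_batches):
                for _ in range(config.critic_steps):
                    idx = rng.choice(len(group), size=min(config.batch_size, len(group)),
                                     replace=False)
                    z = Tensor(rng.standard_normal((len(idx), config.latent_dim)))
                    with ad.no_grad():
                        fake = gen(z).data
                    real_b = Tensor(real[idx])
                    gp = gradient_penalty(critic, real_b, fake,
                                          seed=int(rng.integers(2 ** 31)))
                    c_loss, _ = wgan_gp_losses(critic(real_b), critic(Tensor(fake)),
                                               gp, config.gp_weight)
                    c_opt.step(ad.grad(c_loss, critic.parameters()))
                    log["critic_updates"] += 1
                    epoch_ncl.append(-float(c_loss.item()))
                z = Tensor(rng.standard_normal((min(config.batch_size, len(group)),
                                                config.latent_dim)))
                fake = gen(z)
                _, g_loss = wgan_gp_losses(np.zeros(1), critic(fake), 0.0,
                                           config.gp_weight)
                g_opt.step(ad.grad(g_loss, gen.parameters()))
                log["gen_updates"] += 1
            ncl = float(np.mean(epoch_ncl))
            log["neg_critic_loss"].append(ncl)
            if not np.isfinite(ncl):
                raise FloatingPointError("critic loss diverged")
            if ncl < best_ncl - 1e-12:
                best_ncl, best_epoch = ncl, epoch
            if epoch - best_epoch >= config.patience:
                break

        state.generators[label] = gen.state_dict()
        state.critics[label] = critic.state_dict()
        state.training_log[label] = log
        _diversity_warning(gen, config, real, rng)
    return state


def _diversity_warning(gen, config, real, rng, n_check: int = 64):
    """Mode-collapse guard: fake RMS-amplitude spread vs the real data's."""
    with ad.no_grad():
        z = Tensor(rng.standard_normal((n_check, config.latent_dim)))
        fake = gen(z).data
    fake_spread = np.std(np.sqrt((fake ** 2).mean(axis=(1, 2))))
    real_spread = np.std(np.sqrt((real ** 2).mean(axis=(1, 2))))
    if real_spread > 0 and fake_spread < 0.1 * real_spread:
        warnings.warn("possible mode collapse: fake RMS-amplitude spread "
                      f"{fake_spread:.4g} < 10% of real spread {real_spread:.4g}")


# ---------------------------------------------------------------------------
# fake data
# ---------------------------------------------------------------------------

@dataclass
class FakeDataset:
    """Synthesized records standing in for one site's data in evaluations."""

    records: list[ECGRecord]
    source_site: str

    @property
    def size(self) -> int:
        return len(self.records)


def fake_group_sizes(real_counts: dict, n_fake: int) -> dict:
    """Per-group fake counts, proportional to real counts (largest remainder)."""
    total = sum(real_counts.values())
    raw = {k: n_fake * v / total for k, v in real_counts.items()}
    out = {k: int(np.floor(v)) for k, v in raw.items()}
    rema = sorted(raw, key=lambda k: raw[k] - out[k], reverse=True)
    for k in rema[: n_fake - sum(out.values())]:
        out[k] += 1
    return out


def generate_fake_dataset(state: SynthesizerState, demographics_pool: dict,
                          n_per_group: dict, seed: int = 0) -> FakeDataset:
    """Synthesize waveforms and pair them with randomly drawn demographics.

    ``demographics_pool[label]`` is that group's list of real (age, sex)
    pairs; pairs are drawn jointly with replacement, so the joint age-sex
    distribution is preserved while the waveform-demographics linkage stays
    random.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xFA8E]))
    config = state.config
    records = []
    for label, n in n_per_group.items():
        if n == 0:
            continue
        pool = demographics_pool.get(label)
        if not pool:
            raise ValueError(f"empty demographics pool for group {label}")
        gen = state.build_generator(label)
        gen.eval()
        with ad.no_grad():
            z = Tensor(rng.standard_normal((n, config.latent_dim)))
            waves = gen(z).data
        draw = rng.integers(0, len(pool), size=n)
        order = rng.permutation(n)  # random waveform–demographics pairing
        for i in range(n):
            age, sex = pool[draw[i]]
            records.append(ECGRecord(
                waves[order[i]], config.fs, int(age), sex, int(label),
                record_id=f"fake:{state.site_chain[-1]}:g{label}:{i:05d}",
                site_id=f"fake:{state.site_chain[-1]}"))
    return FakeDataset(records, source_site=state.site_chain[-1])


def demographics_pool_of(records) -> dict:
    """Group records' (age, sex) pairs by label, for fake-data pairing."""
    pool = {0: [], 1: []}
    for r in records:
        pool[r.label].append((r.age, r.sex))
    return pool
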