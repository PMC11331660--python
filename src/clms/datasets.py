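"""Multicenter ECG datasets: records, WFDB + CSV readers, preprocessing,
splitting, and the non-IID site-construction procedure.

A record is a 12-lead (configurable) waveform with the patient's age, sex and
a binary arrhythmia label.  A :class:`SiteDataset` is one institution's
collection with disjoint train/val/test partitions.  Site construction for the
"weak" multicenter setting partitions a single cohort into four demographically
skewed sites: the cohort is split into four groups by an age cutoff and sex,
each group is cut into random near-equal subgroups, and each group donates a
few subgroups to the other groups so that every site mixes all four strata
while remaining dominated by its own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

MALE, FEMALE = "male", "female"
_SEX_ALIASES = {"male": MALE, "m": MALE, "1": MALE,
                "female": FEMALE, "f": FEMALE, "0": FEMALE}


@dataclass
class ECGRecord:
    """One subject's multichannel waveform (mV) plus demographics and label."""

    waveform: np.ndarray  # (leads, samples)
    sampling_rate: float
    age: int
    sex: str
    label: int
    record_id: str
    site_id: str = ""

    def __post_init__(self):
        self.waveform = np.asarray(self.waveform, dtype=np.float64)
        if self.waveform.ndim != 2:
            raise ValueError("waveform must be a leads × samples matrix")
        if self.label not in (0, 1):
            raise ValueError("label must be binary")
        if self.sex not in (MALE, FEMALE):
            raise ValueError(f"sex must be '{MALE}' or '{FEMALE}'")


@dataclass
class SiteDataset:
    """One institution's records with optional train/val/test partitions."""

    records: list[ECGRecord]
    site_id: str = ""
    partitions: dict = field(default_factory=dict)

    @property
    def size_n(self) -> int:
        return len(self.records)

    def subset(self, part: str) -> list[ECGRecord]:
        return [self.records[i] for i in self.partitions[part]]

    def validate_partitions(self):
        if not self.partitions:
            return
        idx = np.concatenate([np.asarray(v, dtype=int) for v in self.partitions.values()])
        if len(set(idx.tolist())) != len(idx) or sorted(idx.tolist()) != list(range(self.size_n)):
            raise ValueError("partitions must be disjoint and cover all records")

    # -- serialization (NPZ) ----------------------------------------------
    def save_npz(self, path):
        wf = np.stack([r.waveform for r in self.records])
        np.savez_compressed(
            path,
            waveforms=wf,
            sampling_rate=np.array([self.records[0].sampling_rate]),
            ages=np.array([r.age for r in self.records]),
            sexes=np.array([r.sex for r in self.records]),
            labels=np.array([r.label for r in self.records]),
            record_ids=np.array([r.record_id for r in self.records]),
            site_id=np.array([self.site_id]),
            **{f"part_{k}": np.asarray(v, dtype=int) for k, v in self.partitions.items()},
        )

    @classmethod
    def load_npz(cls, path) -> "SiteDataset":
        z = np.load(path, allow_pickle=False)
        site_id = str(z["site_id"][0])
        fs = float(z["sampling_rate"][0])
        records = [
            ECGRecord(z["waveforms"][i], fs, int(z["ages"][i]), str(z["sexes"][i]),
                      int(z["labels"][i]), str(z["record_ids"][i]), site_id)
            for i in range(z["waveforms"].shape[0])
        ]
        parts = {k[5:]: z[k] for k in z.files if k.startswith("part_")}
        return cls(records, site_id, parts)


# ---------------------------------------------------------------------------
# WFDB input/output (format 16)
# ---------------------------------------------------------------------------
# The standard WFDB distribution of the source databases is a text header
# (.hea) naming a 16-bit signal file (.dat), sample-interleaved, with
# per-signal gain (adc units per mV) and baseline.

_DEFAULT_GAIN = 1000.0


def write_wfdb_record(directory, record_id: str, waveform: np.ndarray, fs: float,
                      lead_names=None):
    """Write one record as a .hea/.dat pair (format 16, gain 1000 adu/mV)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    waveform = np.asarray(waveform, dtype=np.float64)
    n_sig, n_samp = waveform.shape
    lead_names = lead_names or [f"lead{i}" for i in range(n_sig)]
    adc = np.clip(np.round(waveform * _DEFAULT_GAIN), -32768, 32767).astype("<i2")
    adc.T.reshape(-1).tofile(directory / f"{record_id}.dat")
    lines = [f"{record_id} {n_sig} {fs:g} {n_samp}"]
    for i in range(n_sig):
        lines.append(
            f"{record_id}.dat 16 {_DEFAULT_GAIN:g}(0)/mV 16 0 "
            f"{int(adc[i, 0])} 0 0 {lead_names[i]}")
    (directory / f"{record_id}.hea").write_text("\n".join(lines) + "\n")


def read_wfdb_record(header_path) -> tuple[np.ndarray, float, str]:
    """Read a format-16 .hea/.dat pair; returns (waveform mV, fs, record_id)."""
    header_path = Path(header_path)
    lines = [ln for ln in header_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    rec_name, n_sig, fs = lines[0].split()[0], int(lines[0].split()[1]), float(lines[0].split()[2])
    n_samp = int(lines[0].split()[3])
    gains, baselines, dat_name = [], [], None
    for ln in lines[1:1 + n_sig]:
        fields = ln.split()
        dat_name = fields[0]
        if fields[1] != "16":
            raise ValueError(f"unsupported WFDB format {fields[1]!r} in {header_path}")
        gain_spec = fields[2]
        base = 0.0
        if "(" in gain_spec:
            gain = float(gain_spec.split("(")[0])
            base = float(gain_spec.split("(")[1].split(")")[0])
        else:
            gain = float(gain_spec.split("/")[0])
        gains.append(gain if gain != 0 else _DEFAULT_GAIN)
        baselines.append(base)
    raw = np.fromfile(header_path.parent / dat_name, dtype="<i2")
    if raw.size != n_sig * n_samp:
        raise ValueError(f"signal file size mismatch for {header_path}")
    adc = raw.reshape(n_samp, n_sig).T.astype(np.float64)
    wave = (adc - np.array(baselines)[:, None]) / np.array(gains)[:, None]
    return wave, fs, rec_name


def read_wfdb_dataset(path, demographics, site_id: str = "") -> SiteDataset:
    """Read a directory of WFDB records joined with a demographics CSV.

    The CSV must have columns ``record_id, age, sex, label``.  Records with
    missing demographics are dropped (counted in a warning); unreadable
    headers are skipped with a warning.
    """
    path = Path(path)
    demo = pd.read_csv(demographics, dtype={"record_id": str})
    demo = demo.set_index("record_id")
    records, dropped = [], 0
    for hea in sorted(path.glob("*.hea")):
        try:
            wave, fs, rec_id = read_wfdb_record(hea)
        except Exception as exc:  # unreadable header/signal
            warnings.warn(f"skipping unreadable record {hea.name}: {exc}")
            continue
        if rec_id not in demo.index:
            dropped += 1
            continue
        row = demo.loc[rec_id]
        if row[["age", "sex", "label"]].isna().any():
            dropped += 1
            continue
        sex = _SEX_ALIASES.get(str(row["sex"]).strip().lower())
        if sex is None:
            dropped += 1
            continue
        records.append(ECGRecord(wave, fs, int(row["age"]), sex,
                                 int(row["label"]), rec_id, site_id))
    if dropped:
        warnings.warn(f"dropped {dropped} records with missing demographics")
    if not records:
        raise ValueError(f"no readable records with demographics under {path}")
    ds = SiteDataset(records, site_id)
    ds.dropped_count = dropped
    return ds


def write_wfdb_dataset(dataset: SiteDataset, directory, demographics_csv):
    """Emit a SiteDataset in the same on-disk layout read_wfdb_dataset consumes."""
    directory = Path(directory)
    rows = []
    for r in dataset.records:
        write_wfdb_record(directory, r.record_id, r.waveform, r.sampling_rate)
        rows.append({"record_id": r.record_id, "age": r.age, "sex": r.sex,
                     "label": r.label})
    pd.DataFrame(rows).to_csv(demographics_csv, index=False)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def filter_by_age(records: list[ECGRecord], min_age: int = 18,
                  max_age: int = 100) -> list[ECGRecord]:
    """Keep records with min_age ≤ age ≤ max_age (inclusive), order preserved."""
    if min_age > max_age:
        raise ValueError("min_age must not exceed max_age")
    return [r for r in records if min_age <= r.age <= max_age]


def bandpass_filter(waveform: np.ndarray, low: float = 0.5, high: float = 40.0,
                    order: int = 5, fs: float = 500.0) -> np.ndarray:
    """Zero-phase Butterworth bandpass, each lead filtered independently."""
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= fs / 2:
        raise ValueError("high cutoff must be below the Nyquist frequency")
    if order < 1:
        raise ValueError("order must be >= 1")
    sos = butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(waveform, dtype=np.float64), axis=-1)


def minmax_scale(waveform: np.ndarray, per_lead: bool = False) -> np.ndarray:
    """Affine map of the record to [−1, 1]; constant input maps to zeros.

    By default the min/max are taken over the whole record so relative lead
    amplitudes are preserved; ``per_lead=True`` rescales each lead separately.
    """
    w = np.asarray(waveform, dtype=np.float64)
    axis = -1 if per_lead else None
    lo = w.min(axis=axis, keepdims=True)
    hi = w.max(axis=axis, keepdims=True)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 2.0 * (w - lo) / span - 1.0
    return np.where(span == 0, 0.0, out)


def preprocess_record(record: ECGRecord, low=0.5, high=40.0, order=5,
                      per_lead: bool = False) -> ECGRecord:
    """Filter then scale one record (the per-record preprocessing pipeline)."""
    wave = bandpass_filter(record.waveform, low, high, order, record.sampling_rate)
    wave = minmax_scale(wave, per_lead=per_lead)
    return ECGRecord(wave, record.sampling_rate, record.age, record.sex,
                     record.label, record.record_id, record.site_id)


def preprocess_site(site: SiteDataset, **kwargs) -> SiteDataset:
    return SiteDataset([preprocess_record(r, **kwargs) for r in site.records],
                       site.site_id, dict(site.partitions))


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_dataset(dataset: SiteDataset, ratios=(8, 1, 1), seed: int = 0,
                  stratify: bool = False) -> SiteDataset:
    """Random train/val/test partition (default 8:1:1); remainder to train.

    Deterministic under ``seed``.  With ``stratify=True`` the split is done
    within each label class before merging.
    """
    if any(r <= 0 for r in ratios) or len(ratios) != 3:
        raise ValueError("ratios must be three positive numbers")
    n = dataset.size_n
    if n < 3:
        raise ValueError("need at least 3 records to split")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5917]))

    def _split_indices(indices):
        m = len(indices)
        total = sum(ratios)
        n_val = int(m * ratios[1] / total)
        n_test = int(m * ratios[2] / total)
        perm = rng.permutation(indices)
        return (perm[n_val + n_test:], perm[:n_val], perm[n_val:n_val + n_test])

    if stratify:
        labels = np.array([r.label for r in dataset.records])
        parts = [[], [], []]
        for lab in np.unique(labels):
            sub = np.flatnonzero(labels == lab)
            for i, part in enumerate(_split_indices(sub)):
                parts[i].append(part)
        train, val, test = (np.concatenate(p) for p in parts)
    else:
        train, val, test = _split_indices(np.arange(n))
    if len(train) == 0 or len(val) == 0 or len(test) == 0:
        raise ValueError("a partition is empty; dataset too small for these ratios")
    out = SiteDataset(dataset.records, dataset.site_id,
                      {"train": np.sort(train), "val": np.sort(val), "test": np.sort(test)})
    out.validate_partitions()
    return out


def generate_noniid_sites(dataset: SiteDataset, age_cut: int = 60,
                          n_subgroups: int = 10, n_transfer: int = 3,
                          seed: int = 0) -> list[SiteDataset]:
    """Partition one cohort into four demographically non-IID sites.

    Groups: (age < cut, female), (age < cut, male), (age ≥ cut, female),
    (age ≥ cut, male).  Each group is cut into ``n_subgroups`` near-equal
    random subgroups; ``n_transfer`` randomly chosen subgroups are donated,
    assigned round-robin to the other three groups in fixed group order.
    """
    if not n_subgroups > n_transfer >= 3:
        raise ValueError("need n_subgroups > n_transfer >= 3")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x401d]))
    group_names = ["young_female", "young_male", "old_female", "old_male"]

    def group_of(r: ECGRecord) -> int:
        return (0 if r.age < age_cut else 2) + (1 if r.sex == MALE else 0)

    groups = [[] for _ in range(4)]
    for i, r in enumerate(dataset.records):
        groups[group_of(r)].append(i)
    for gi, g in enumerate(groups):
        if len(g) < n_subgroups:
            raise ValueError(
                f"group '{group_names[gi]}' has {len(g)} records; "
                f"cannot form {n_subgroups} subgroups")

    site_indices = [[] for _ in range(4)]
    for gi, g in enumerate(groups):
        perm = rng.permutation(g)
        subgroups = np.array_split(perm, n_subgroups)
        donated = rng.choice(n_subgroups, size=n_transfer, replace=False)
        recipients = [k for k in range(4) if k != gi]  # fixed group order
        for j, si in enumerate(donated):
            site_indices[recipients[j % 3]].extend(subgroups[si].tolist())
        for si in range(n_subgroups):
            if si not in donated:
                site_indices[gi].extend(subgroups[si].tolist())

    sites = []
    for k, idx in enumerate(site_indices):
        recs = [ECGRecord(dataset.records[i].waveform, dataset.records[i].sampling_rate,
                          dataset.records[i].age, dataset.records[i].sex,
                          dataset.records[i].label, dataset.records[i].record_id,
                          f"site{k + 1}")
                for i in sorted(idx)]
        sites.append(SiteDataset(recs, f"site{k + 1}"))
    return sites
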