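"""Readers, preprocessing, splitting, and the non-IID site construction."""

import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

from clms.datasets import (ECGRecord, SiteDataset, bandpass_filter,
                           filter_by_age, generate_noniid_sites, minmax_scale,
                           read_wfdb_dataset, split_dataset,
                           write_wfdb_dataset)
from clms.synthetic import SimConfig, SiteProfile, simulate_site


def _record(age=50, sex="male", label=0, rid="r0", n=40):
    return ECGRecord(np.zeros((2, n)), 100.0, age, sex, label, rid)


# ---------------------------------------------------------------------------
# age filter
# ---------------------------------------------------------------------------

def test_age_filter_is_inclusive_at_both_bounds():
    recs = [_record(age=a, rid=f"r{a}") for a in (17, 18, 100, 101)]
    kept = filter_by_age(recs, 18, 100)
    assert [r.age for r in kept] == [18, 100]


def test_age_filter_empty_input_and_bad_bounds():
    assert filter_by_age([], 18, 100) == []
    with pytest.raises(ValueError):
        filter_by_age([], 50, 40)


@given(st.lists(st.integers(min_value=0, max_value=120), max_size=60))
def test_age_filter_equals_brute_force(ages):
    recs = [_record(age=a, rid=f"r{i}") for i, a in enumerate(ages)]
    kept = filter_by_age(recs, 18, 100)
    assert [r.record_id for r in kept] == \
        [r.record_id for r in recs if 18 <= r.age <= 100]


# ---------------------------------------------------------------------------
# bandpass filter
# ---------------------------------------------------------------------------

def _sine(freq, fs=500.0, seconds=4.0):
    t = np.arange(int(fs * seconds)) / fs
    return np.sin(2 * np.pi * freq * t)[None, :]


def test_bandpass_removes_dc_offset():
    out = bandpass_filter(np.full((3, 2000), 3.0), fs=500.0)
    assert np.all(np.abs(out.mean(axis=1)) < 1e-3)


def test_bandpass_passes_in_band_and_attenuates_out_of_band():
    inb = _sine(10.0)
    rms = lambda x: np.sqrt((x ** 2).mean())
    assert abs(rms(bandpass_filter(inb, fs=500.0)) - rms(inb)) < 0.05 * rms(inb)
    mains = _sine(60.0)
    assert rms(bandpass_filter(mains, fs=500.0)) < 0.2 * rms(mains)


def test_bandpass_is_linear():
    rng = np.random.default_rng(0)
    x, y = rng.normal(size=(2, 500)), rng.normal(size=(2, 500))
    lhs = bandpass_filter(2.0 * x + 3.0 * y, fs=125.0)
    rhs = 2.0 * bandpass_filter(x, fs=125.0) + 3.0 * bandpass_filter(y, fs=125.0)
    assert np.allclose(lhs, rhs, atol=1e-9)


def test_bandpass_rejects_cutoff_at_nyquist():
    with pytest.raises(ValueError):
        bandpass_filter(np.zeros((1, 100)), low=0.5, high=70.0, fs=125.0)


# ---------------------------------------------------------------------------
# min-max scaling
# ---------------------------------------------------------------------------

def test_minmax_symmetric_record_is_fixed_point():
    w = np.linspace(-2, 2, 50).reshape(2, 25)
    out = minmax_scale(w)
    assert np.isclose(out.min(), -1) and np.isclose(out.max(), 1)
    assert np.allclose(out, w / 2.0)


def test_minmax_affine_map_and_constant_degenerate():
    w = np.linspace(0, 4, 21).reshape(1, 21)  # contains 2.0 exactly
    out = minmax_scale(w)
    assert np.isclose(out.min(), -1) and np.isclose(out.max(), 1)
    assert np.isclose(out[0, 10], 0.0)  # midpoint 2 maps to 0
    assert np.all(minmax_scale(np.full((3, 10), 7.0)) == 0.0)


@given(st.integers(0, 2 ** 31 - 1))
def test_minmax_attains_both_endpoints_for_nonconstant_input(seed):
    w = np.random.default_rng(seed).normal(size=(3, 30))
    out = minmax_scale(w)
    assert out.min() == -1.0 and out.max() == 1.0
    assert np.all((out >= -1) & (out <= 1))


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def _dataset(n, seed=0):
    rng = np.random.default_rng(seed)
    recs = [_record(age=int(rng.integers(20, 90)),
                    sex="male" if rng.random() < 0.5 else "female",
                    label=int(rng.random() < 0.5), rid=f"r{i}")
            for i in range(n)]
    return SiteDataset(recs, "s")


def test_split_ratio_sizes_and_determinism():
    ds = split_dataset(_dataset(10), (8, 1, 1), seed=3)
    assert tuple(len(ds.partitions[k]) for k in ("train", "val", "test")) == (8, 1, 1)
    ds2 = split_dataset(_dataset(100), seed=5)
    ds3 = split_dataset(_dataset(100), seed=5)
    for k in ("train", "val", "test"):
        assert np.array_equal(ds2.partitions[k], ds3.partitions[k])


def test_split_counting_and_conservation_n97():
    ds = split_dataset(_dataset(97), seed=1)
    sizes = {k: len(v) for k, v in ds.partitions.items()}
    assert sizes == {"train": 79, "val": 9, "test": 9}
    ds.validate_partitions()  # disjoint cover


def test_split_errors_on_empty_partition():
    with pytest.raises(ValueError):
        split_dataset(_dataset(2), seed=0)


# ---------------------------------------------------------------------------
# non-IID site construction
# ---------------------------------------------------------------------------

def _balanced_cohort(per_group=100):
    recs = []
    i = 0
    for age, sex in [(40, "female"), (40, "male"), (70, "female"), (70, "male")]:
        for _ in range(per_group):
            recs.append(_record(age=age, sex=sex, label=i % 2, rid=f"r{i}"))
            i += 1
    return SiteDataset(recs, "cohort")


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_noniid_counting_with_four_equal_groups(seed):
    sites = generate_noniid_sites(_balanced_cohort(100), seed=seed)
    assert [s.size_n for s in sites] == [100, 100, 100, 100]


def test_noniid_partitions_input_exactly_and_mixes_all_groups():
    ds = _balanced_cohort(40)
    sites = generate_noniid_sites(ds, seed=4)
    all_ids = sorted(r.record_id for s in sites for r in s.records)
    assert all_ids == sorted(r.record_id for r in ds.records)
    for s in sites:
        strata = {(r.age < 60, r.sex) for r in s.records}
        assert len(strata) == 4  # every site contains all demographic groups


def test_noniid_errors_name_the_small_group():
    ds = _balanced_cohort(40)
    small = SiteDataset([r for r in ds.records if not (r.age >= 60 and r.sex == "male")]
                        + [r for r in ds.records if r.age >= 60 and r.sex == "male"][:5],
                        "c")
    with pytest.raises(ValueError, match="old_male"):
        generate_noniid_sites(small, seed=0)
    with pytest.raises(ValueError):
        generate_noniid_sites(ds, n_subgroups=3, n_transfer=3, seed=0)


# ---------------------------------------------------------------------------
# WFDB input/output
# ---------------------------------------------------------------------------

def test_wfdb_round_trip_matches_within_write_precision(tmp_path, tiny_sim_config):
    prof = SiteProfile(n=5, site_id="wf")
    site = simulate_site(prof, tiny_sim_config, seed=11)
    write_wfdb_dataset(site, tmp_path, tmp_path / "demographics.csv")
    back = read_wfdb_dataset(tmp_path, tmp_path / "demographics.csv", site_id="wf")
    assert back.size_n == 5
    orig = {r.record_id: r for r in site.records}
    for r in back.records:
        o = orig[r.record_id]
        assert np.allclose(r.waveform, o.waveform, atol=1e-3)  # 16-bit @ 1000 adu/mV
        assert (r.age, r.sex, r.label) == (o.age, o.sex, o.label)


def test_wfdb_reader_drops_incomplete_and_skips_unreadable(tmp_path, tiny_sim_config):
    site = simulate_site(SiteProfile(n=3, site_id="wf"), tiny_sim_config, seed=12)
    write_wfdb_dataset(site, tmp_path, tmp_path / "demo.csv")
    # remove one record's age
    text = (tmp_path / "demo.csv").read_text().splitlines()
    parts = text[1].split(",")
    parts[1] = ""
    text[1] = ",".join(parts)
    (tmp_path / "demo.csv").write_text("\n".join(text))
    # corrupt one header
    (tmp_path / "broken.hea").write_text("broken 1 oops\n")
    with warnings.catch_warnings(record=True):
        warnings.simplefilter("always")
        ds = read_wfdb_dataset(tmp_path, tmp_path / "demo.csv")
    assert ds.size_n == 2 and ds.dropped_count == 1


def test_wfdb_reader_errors_on_empty_directory(tmp_path):
    (tmp_path / "demo.csv").write_text("record_id,age,sex,label\n")
    with pytest.raises(ValueError):
        read_wfdb_dataset(tmp_path, tmp_path / "demo.csv")
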