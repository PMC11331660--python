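"""Method-selection mechanics and the multicenter driver."""

import numpy as np
import pytest

from clms.cl_methods import MethodState
from clms.datasets import SiteDataset
from clms.generative import SynthConfig
from clms.metrics import SiteMetric
from clms.model import Detector
from clms.selection import (Handoff, SelectionConfig, SelectionHistory,
                            evaluate_on_fake, finetune_baseline, order_sites,
                            run_multicenter, select_method, train_with_method)
from clms.training import TrainResult, TrainSettings, train_detector


def _fast_sel(seed=0, epochs=4):
    ts = TrainSettings(epochs=epochs, patience=epochs, lr=1e-3, batch_size=32, seed=seed)
    return SelectionConfig(max_decay_steps=4, n_fake_cap=32, train_settings=ts)


@pytest.fixture(scope="module")
def site1_state(shift_sites, tiny_detector_config):
    from clms.selection import _handoff_method_state
    config = _fast_sel()
    model = Detector(tiny_detector_config)
    res = train_detector(model, shift_sites[0], config.train_settings)
    return res, _handoff_method_state(model, shift_sites[0], config, n_importance=16)


# ---------------------------------------------------------------------------
# configuration and pure selection logic
# ---------------------------------------------------------------------------

def test_threshold_modes():
    assert SelectionConfig().threshold(0.8) == pytest.approx(0.05 * 0.8)
    frac = SelectionConfig(reference_mode="fraction_retained")
    assert frac.threshold(0.8) == pytest.approx(0.95 * 0.8)
    with pytest.raises(ValueError):
        SelectionConfig(alpha=1.5)
    with pytest.raises(ValueError):
        SelectionConfig(reference_mode="nope")


def _result(score):
    return TrainResult(params=np.array([score]), best_val_metric=0.5)


def test_select_method_argmax_and_tie_break():
    res = {"LwF": (_result(1), 0.70), "EWC": (_result(2), 0.80), "MAS": (_result(3), 0.75)}
    assert select_method(res)[0] == "EWC"
    assert select_method({"MAS": (_result(3), 0.5)})[0] == "MAS"
    tie = {"LwF": (_result(1), 0.75), "EWC": (_result(2), 0.60), "MAS": (_result(3), 0.75)}
    assert select_method(tie, ("LwF", "EWC", "MAS"))[0] == "LwF"
    with pytest.raises(ValueError):
        select_method({})


def test_order_sites_by_size_with_id_tie_break():
    sites = [SiteDataset([None] * n, sid) for n, sid in
             [(5, "b"), (3, "c"), (9, "a"), (3, "a")]]
    small = order_sites(sites, "small_to_large")
    assert [(s.size_n, s.site_id) for s in small] == [(3, "a"), (3, "c"), (5, "b"), (9, "a")]
    large = order_sites(sites, "large_to_small")
    assert [s.size_n for s in large] == [9, 5, 3, 3]
    with pytest.raises(ValueError):
        order_sites(sites, "random")


def test_selection_history_rejects_non_optimal_choice():
    h = SelectionHistory()
    with pytest.raises(ValueError):
        h.add("s2", {"LwF": 0.9, "EWC": 0.8}, "EWC", {}, 0.7)
    h.add("s2", {"LwF": 0.9, "EWC": 0.8}, "LwF", {"LwF": 1.0}, 0.7)
    assert len(h.entries) == 1


# ---------------------------------------------------------------------------
# Algorithm steps on real (tiny) training
# ---------------------------------------------------------------------------

def test_lambda_trace_is_geometric_when_reference_unreachable(
        shift_sites, tiny_detector_config, site1_state):
    res1, state1 = site1_state
    config = _fast_sel(epochs=2)
    cand, _ = train_with_method(res1.state, shift_sites[1], "EWC", state1,
                                p_star=0.9, config=config,
                                detector_config=tiny_detector_config,
                                threshold=1.01)
    lams = [l for l, _ in cand.decay_trace]
    assert np.allclose(lams, [1.0, 0.9, 0.81, 0.729])
    assert cand.hyperparams.get("decay_exhausted") is True


def test_permissive_default_threshold_keeps_lambda_at_one(
        shift_sites, tiny_detector_config, site1_state):
    res1, state1 = site1_state
    cand, _ = train_with_method(res1.state, shift_sites[1], "MAS", state1,
                                p_star=res1.best_val_metric, config=_fast_sel(),
                                detector_config=tiny_detector_config)
    assert len(cand.decay_trace) == 1 and cand.hyperparams["lambda"] == 1.0


def test_zero_lambda_candidate_equals_plain_finetuning_bitwise(
        shift_sites, tiny_detector_config, site1_state):
    res1, state1 = site1_state
    config = _fast_sel()
    config.lambda_init = 0.0
    base = finetune_baseline(res1.state, shift_sites[1], config, tiny_detector_config)
    cand, _ = train_with_method(res1.state, shift_sites[1], "EWC", state1,
                                base.best_val_metric, config, tiny_detector_config)
    assert np.array_equal(base.params, cand.params)
    assert base.best_val_metric == cand.best_val_metric


def test_unknown_method_is_rejected(shift_sites, tiny_detector_config, site1_state):
    res1, state1 = site1_state
    with pytest.raises(ValueError):
        train_with_method(res1.state, shift_sites[1], "SI", state1, 0.5,
                          _fast_sel(), tiny_detector_config)


def test_chance_level_baseline_on_label_independent_waveforms(tiny_detector_config):
    """Labels drawn independently of waveforms: held-out AUROC stays near 0.5.

    The band is ±3 binomial standard errors for the held-out size (30
    records), the honest chance band at this granularity.
    """
    from clms.datasets import filter_by_age, preprocess_site, split_dataset
    from clms.synthetic import SimConfig, SiteProfile, simulate_site
    from clms.training import evaluate_auroc
    import copy
    prof = SiteProfile(n=150, arrhythmia_prevalence=0.5, site_id="null")
    site = simulate_site(prof, SimConfig(fs=125.0, duration=2.4), seed=30)
    rng = np.random.default_rng(31)
    records = [copy.copy(r) for r in site.records]
    for r in records:  # sever the label–waveform link entirely
        r.label = int(rng.random() < 0.5)
    if len({r.label for r in records}) < 2:  # pragma: no cover
        records[0].label = 1 - records[0].label
    null_site = split_dataset(preprocess_site(SiteDataset(
        filter_by_age(records), "null")), seed=32)
    model = Detector(tiny_detector_config)
    train_detector(model, null_site, TrainSettings(epochs=6, patience=6,
                                                   lr=1e-3, batch_size=32, seed=33))
    held_out = null_site.subset("val") + null_site.subset("test")
    assert 0.2 < evaluate_auroc(model, held_out) < 0.8


# ---------------------------------------------------------------------------
# fake-data evaluation
# ---------------------------------------------------------------------------

def _fake_set(records, source):
    from clms.generative import FakeDataset
    return FakeDataset(records, source)


def test_evaluate_on_fake_weighted_mean_and_single_class_skip(
        one_site, tiny_detector_config, site1_state):
    import warnings as _w
    res1, _ = site1_state
    recs = one_site.subset("train")
    pos = [r for r in recs if r.label == 1]
    with _w.catch_warnings(record=True) as caught:
        _w.simplefilter("always")
        with pytest.raises(ValueError):
            evaluate_on_fake(res1.state, [_fake_set(pos, "only-pos")],
                             tiny_detector_config)
    assert any("single class" in str(c.message) for c in caught)
    score = evaluate_on_fake(res1.state, [_fake_set(recs, "mixed")],
                             tiny_detector_config)
    assert 0.0 <= score <= 1.0


def test_weighted_fake_average_matches_hand_value():
    from clms.metrics import weighted_auroc
    assert weighted_auroc([SiteMetric("a", 100, 0.8),
                           SiteMetric("b", 300, 0.9)]) == pytest.approx(0.875)


# ---------------------------------------------------------------------------
# multicenter driver
# ---------------------------------------------------------------------------

class _AccessLoggingSite:
    """Duck-typed SiteDataset wrapper that records which site's data is read."""

    def __init__(self, site, log):
        self._site, self._log = site, log

    @property
    def records(self):
        self._log.append(self._site.site_id)
        return self._site.records

    def subset(self, part):
        self._log.append(self._site.site_id)
        return self._site.subset(part)

    @property
    def site_id(self):
        return self._site.site_id

    @property
    def partitions(self):
        return self._site.partitions

    @property
    def size_n(self):
        return self._site.size_n

    def validate_partitions(self):
        return self._site.validate_partitions()


@pytest.fixture(scope="module")
def tiny_two_site_run(shift_sites, tiny_detector_config):
    config = _fast_sel(seed=1)
    synth = SynthConfig.tiny(out_len=300, seed=1)
    synth.epochs = 3
    log = []
    wrapped = [_AccessLoggingSite(s, log) for s in shift_sites[:2]]
    state, history = run_multicenter(wrapped, config, synth, tiny_detector_config,
                                     seed=1, check_privacy=False,
                                     keep_stage_states=True)
    return state, history, log


def test_two_site_run_records_one_selection(tiny_two_site_run):
    _, history, _ = tiny_two_site_run
    assert len(history.entries) == 1
    entry = history.entries[0]
    assert entry["chosen"] in ("LwF", "EWC", "MAS")
    assert set(entry["fake_scores"]) == {"LwF", "EWC", "MAS"}
    assert len(history.stage_states) == 2


def test_sites_are_read_only_during_their_own_turn(tiny_two_site_run):
    _, _, log = tiny_two_site_run
    blocks = [sid for i, sid in enumerate(log) if i == 0 or log[i - 1] != sid]
    assert blocks == ["site1", "site2"]  # contiguous, in processing order


def test_handoff_privacy_assertion(shift_sites, tiny_detector_config,
                                   site1_state, tmp_path):
    res1, state1 = site1_state
    from clms.generative import (demographics_pool_of, generate_fake_dataset,
                                 train_synthesizer)
    synth = SynthConfig.tiny(out_len=300, seed=2)
    synth.epochs = 2
    st = train_synthesizer(shift_sites[0], synth, seed=2)
    fake = generate_fake_dataset(st, demographics_pool_of(shift_sites[0].subset("train")),
                                 {0: 8, 1: 8}, seed=2)
    handoff = Handoff(res1.state, state1, st, [fake])
    handoff.assert_no_raw_records(shift_sites)  # passes: no raw data crosses

    leaked = shift_sites[0].records[0]
    fake.records[0].waveform = leaked.waveform.copy()
    with pytest.raises(AssertionError, match="bit-identical"):
        handoff.assert_no_raw_records(shift_sites)
    fake.records[0].record_id = leaked.record_id
    with pytest.raises(AssertionError):
        handoff.assert_no_raw_records(shift_sites)

    handoff.save(tmp_path / "handoff")
    import json
    manifest = json.loads((tmp_path / "handoff" / "manifest.json").read_text())
    assert manifest["synthetic"] is True and manifest["files"]


def test_multicenter_requires_two_sites(shift_sites, tiny_detector_config):
    with pytest.raises(ValueError):
        run_multicenter(shift_sites[:1], _fast_sel(),
                        SynthConfig.tiny(out_len=300), tiny_detector_config)
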