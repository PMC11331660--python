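import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")

from clms.datasets import SiteDataset, filter_by_age, preprocess_site, split_dataset
from clms.model import DetectorConfig
from clms.synthetic import (SimConfig, SiteProfile, simulate_scenario,
                            simulate_site, strong_shift_scenario)


@pytest.fixture(scope="session")
def tiny_sim_config():
    return SimConfig(fs=125.0, duration=2.4)


@pytest.fixture(scope="session")
def tiny_detector_config():
    return DetectorConfig.tiny(input_samples=300, seed=0)


def _prepared_sites(seed: int, n_per_site: int = 64, n_sites: int = 3):
    sites = simulate_scenario(strong_shift_scenario(n_sites, n_per_site=n_per_site),
                              seed=seed)
    return [split_dataset(preprocess_site(SiteDataset(filter_by_age(s.records),
                                                      s.site_id)), seed=seed + 1)
            for s in sites]


@pytest.fixture(scope="session")
def shift_sites():
    """Three small preprocessed sites with strong domain shift (seed 0)."""
    return _prepared_sites(0)


@pytest.fixture(scope="session")
def one_site(tiny_sim_config):
    """One balanced, learnable site (seed 7), preprocessed and split."""
    prof = SiteProfile(n=80, arrhythmia_prevalence=0.5, rr_cv_normal=0.03,
                       rr_cv_arrhythmia=0.25, noise_sd=0.02, site_id="solo")
    site = simulate_site(prof, tiny_sim_config, seed=7)
    site = SiteDataset(filter_by_age(site.records), site.site_id)
    return split_dataset(preprocess_site(site), seed=8)
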