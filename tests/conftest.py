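import warnings

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import reprophen as rp

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_screen_config():
    return rp.ScreenSimConfig(
        n_plates=2, wells_per_plate=24, n_replicates=2, n_targets=20,
        n_nt_controls_per_plate=2, n_features=8, n_classes=3,
        class_proportions=(0.4, 0.4, 0.2), seed=11)


@pytest.fixture(scope="session")
def small_screen(small_screen_config):
    return rp.generate_screen(small_screen_config)


@pytest.fixture(scope="session")
def small_profiles(small_screen):
    from reprophen import normalize as nz
    tables, truth = small_screen
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ps = nz.average_replicates(nz.zscore_screen(tables))
    return ps, truth


@pytest.fixture(scope="session")
def small_trajectory_config():
    prog = tuple([5.7] + list(np.linspace(2.5, 6.8, 7)))
    off = (0.0, 0.0, 1.0, 2.0, 0.5, 3.0, 1.5, 2.5)
    return rp.TrajectorySimConfig(
        n_genes=400, replicates_per_day=2, n_knockdowns=8,
        planted_progression=prog, orthogonal_offset=off,
        replicates_per_knockdown=2, library_size=100_000, seed=5)


@pytest.fixture(scope="session")
def small_timecourse(small_trajectory_config):
    return rp.generate_timecourse(small_trajectory_config)
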