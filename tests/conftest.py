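import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import grsgdm as g

settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fpg_panel():
    return g.packaged_panel("FPG")


@pytest.fixture(scope="session")
def t2d_panel():
    return g.packaged_panel("T2D")


@pytest.fixture(scope="session")
def fpg_panel_hapo():
    return g.packaged_panel("FPG", cohort="HAPO")


@pytest.fixture(scope="session")
def t2d_panel_hapo():
    return g.packaged_panel("T2D", cohort="HAPO")


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared by read-only tests."""
    cfg = g.SimConfig(n_samples=800, seed=42)
    return cfg, g.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_scores(small_cohort, fpg_panel_hapo, t2d_panel_hapo):
    _, cohort = small_cohort
    return g.scores_frame(g.score_cohort(cohort.genotypes, fpg_panel_hapo),
                          g.score_cohort(cohort.genotypes, t2d_panel_hapo))
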