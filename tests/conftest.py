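import warnings

import numpy as np
import pytest

import lesionatoms as la

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def scheme():
    return la.canonical_scheme()


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across read-only tests."""
    cfg = la.SimConfig(seed=42)
    cohort, loads, truth = la.generate_cohort(cfg)
    return cfg, cohort, loads, truth


@pytest.fixture(scope="session")
def small_atlases(scheme):
    """Disjoint gm/wm phantom atlases on a small grid."""
    gm, wm = la.generate_paired_atlases((12, 12, 14), scheme, seed=5)
    return gm, wm


@pytest.fixture(scope="session")
def single_effect_fit():
    """Posterior for a planted female-only effect (atom 10, delta = 3)."""
    cfg = la.SimConfig(seed=3, beta_female=(0.0,) * 9 + (3.0,),
                       beta_male=(0.0,) * 10)
    _, _, truth = la.generate_cohort(cfg)
    spec = la.ModelSpec(hierarchy="by_sex", draws=2000, seed=11)
    post = la.fit_hierarchical_model(truth.oracle_input, spec)
    return truth, post
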