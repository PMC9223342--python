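import numpy as np
import pytest

from wardstock.synthetic import (
    FixtureSpec,
    build_therapy_trees,
    default_experiment_config,
    make_drug_catalog,
    make_event_logs,
    make_patient_classes,
)

FAST_SOLVER = {"solver_mode": "weighted", "solver_gap": 5e-3, "solver_time_limit": 6.0}


@pytest.fixture(scope="session")
def catalog():
    return make_drug_catalog(FixtureSpec(), seed=0)


@pytest.fixture(scope="session")
def classes():
    return make_patient_classes(seed=0)


@pytest.fixture(scope="session")
def therapy_model(classes, catalog):
    return build_therapy_trees(classes, catalog, seed=0)


@pytest.fixture(scope="session")
def event_logs(classes, therapy_model, catalog):
    """A 2000-day event log sampled from known ground truth."""
    return make_event_logs(classes, therapy_model, catalog, length=2000, seed=1)


@pytest.fixture(scope="session")
def quarter_config():
    """A 12-week study configuration with quick solver settings."""
    from wardstock.controller import calibrate_upsilon_bar

    cfg = default_experiment_config(seed=0, horizon=84)
    for k, v in FAST_SOLVER.items():
        setattr(cfg, k, v)
    cfg.upsilon_bar = calibrate_upsilon_bar(cfg)
    return cfg


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
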