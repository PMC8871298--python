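import warnings

import numpy as np
import pytest

import breathshape as bs
from breathshape.synthetic_data import sensor_ids


@pytest.fixture(scope="session")
def small_sim():
    """A clean 20+25 cohort (no faults) with its preprocessed panels."""
    cfg = bs.SimConfig(
        n_cancer=20, n_control=25, seed=3, outlier_rate=0.0, missing_sensor_rate=0.0
    )
    result = bs.simulate_cohort(cfg)
    cohort = bs.screen_cohort(result.cohort, sensor_ids(cfg.n_sensors))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        panels, reports = bs.preprocess_cohort(cohort)
    return {
        "cfg": cfg,
        "result": result,
        "cohort": cohort,
        "panels": panels,
        "reports": reports,
        "labels": cohort.labels(),
    }


@pytest.fixture(scope="session")
def tiny_panels(small_sim):
    """Three-sensor subset for fast clustering tests."""
    keep = ["GNP01", "GNP02", "MOXA01"]
    return {sid: small_sim["panels"][sid] for sid in keep}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
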