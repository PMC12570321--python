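import numpy as np
import pytest

import lysoratio as lr


@pytest.fixture(scope="session")
def aphid():
    return lr.APHID_LIKE


@pytest.fixture(scope="session")
def unit_probe():
    """Acid-bright logistic running 0 -> 1 with pKa 5.4 and unit slope."""
    return lr.ProbeModel("unit", bottom=0.0, top=1.0, pka=5.4, slope=1.0)


@pytest.fixture(scope="session")
def ph_grid():
    return np.round(np.linspace(1.5, 8.5, 25), 6)


@pytest.fixture(scope="session")
def solution_ratio_titration(aphid, ph_grid):
    """Noiseless solution ratio titration of the acid-bright probe."""
    return lr.simulate_titration(aphid, ph_grid, replicates=1, noise_cv=0.0,
                                 seed=0, assay="ratio")


@pytest.fixture(scope="session")
def anchored_curve(aphid, solution_ratio_titration):
    """Anchored calibration whose scale matches the solution curve."""
    anchor = float(lr.sigmoid_value(aphid, 5.0))
    return lr.build_calibration_anchored(anchor, solution_ratio_titration,
                                         anchor_ph=5.0)


@pytest.fixture
def clean_single_organelle():
    """Noiseless one-organelle field with zero background."""
    cfg = lr.default_config(
        seed=7, n_organelles=1, background=0.0, background_gradient=0.0
    ).without_noise()
    stack, truth = lr.simulate_stack(cfg)
    return cfg, stack, truth
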