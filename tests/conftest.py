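"""Shared fixtures.

The calibration and the three stenosis scenario runs are expensive
(minutes), so they are computed once per session and shared between the
simulation-level tests and the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from stenosim import (ActiveParameters, CircuitParameters, HOParameters,
                      build_geometry)
from stenosim.simulation import (CalibrationTargets, calibrate,
                                 couple_and_run, run_calibrated_scenario,
                                 Scenario)

SEED = 1


@pytest.fixture(scope="session")
def model():
    return build_geometry(seed=SEED)


@pytest.fixture(scope="session")
def passive():
    return HOParameters()


@pytest.fixture(scope="session")
def active():
    return ActiveParameters()


@pytest.fixture(scope="session")
def circuit():
    return CircuitParameters()


@pytest.fixture(scope="session")
def calibration(model, passive, active, circuit):
    return calibrate(CalibrationTargets(), model, passive, active, circuit)


@pytest.fixture(scope="session")
def scenario_results(calibration, model, passive):
    return {
        name: run_calibrated_scenario(name, calibration, model, passive,
                                      dt=5.0e-4)
        for name in ("baseline", "moderate", "severe")
    }


@pytest.fixture(scope="session")
def four_cycle_baseline(calibration, model, passive):
    return couple_and_run(Scenario("baseline"), model, passive,
                          calibration.active, calibration.circuit,
                          tmax_scale=calibration.tmax_scale,
                          passive_scale=calibration.passive_scale,
                          n_cycles=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
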