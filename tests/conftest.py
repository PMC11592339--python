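"""Shared fixtures.

The calibrated model is expensive (a full Nelder–Mead run over six-frequency
sweeps), so it is built once per session and shared by the solver, analysis
and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from rhesusear import (
    BMGradient,
    ElectrodeSpec,
    GreenwoodParams,
    MaterialTable,
    StapesDriveTable,
    build_geometry,
    compare_scenarios,
)
from rhesusear.calibration import ModelBundle, calibrate


@pytest.fixture(scope="session")
def geom():
    return build_geometry()


@pytest.fixture(scope="session")
def mats():
    return MaterialTable()


@pytest.fixture(scope="session")
def gparams():
    return GreenwoodParams()


@pytest.fixture(scope="session")
def drive():
    return StapesDriveTable.default()


@pytest.fixture(scope="session")
def electrode():
    return ElectrodeSpec()


@pytest.fixture(scope="session")
def calibrated(geom, mats, gparams, drive):
    """CalibrationResult of the healthy model from the printed coefficients."""
    return calibrate(ModelBundle(geom, mats, BMGradient()), drive, gparams)


@pytest.fixture(scope="session")
def calibrated_grad(calibrated):
    return calibrated.gradient


@pytest.fixture(scope="session")
def comparison(geom, electrode, mats, calibrated_grad, drive):
    """Three-scenario comparison under the calibrated gradient."""
    return compare_scenarios(
        geom, electrode, mats, calibrated_grad, drive, keep_profiles=True
    )
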