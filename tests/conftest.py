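"""Shared fixtures.

The dendritic-size family experiment (calibration + gain sweep + onset
rapidity for models of 1/5/10/15 mm TDL) is expensive, so it runs once per
session and is shared by the transfer-gain and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from dendrogain import biophysics as bp
from dendrogain import experiments as ex
from dendrogain import morphology as mo
from dendrogain.morphology import Region

FAMILY_TDLS = (1000.0, 5000.0, 10000.0, 15000.0)
FAMILY_SECONDS_PER_FREQ = 25.0
FAMILY_SEED = 0
#: probe set for the small/large cutoff contrast (includes the 3 Hz reference)
CONTRAST_PROBES = np.array(
    [1.0, 3.0, 30.0, 100.0, 160.0, 250.0, 350.0, 450.0, 600.0, 1000.0]
)
#: integration time per probe: long where the large model's threshold
#: crossing lives (and at the F0 reference, which normalizes everything)
CONTRAST_SECONDS = {250.0: 90.0, 350.0: 90.0, 450.0: 90.0, 600.0: 90.0,
                    3.0: 25.0, "default": 15.0}


def passive_config() -> bp.BiophysicsConfig:
    """Reference biophysics with all channel densities zeroed."""
    zero = {r: 0.0 for r in Region}
    return bp.BiophysicsConfig(gna=zero, gk=zero)


def single_soma(radius: float = 10.0) -> mo.Morphology:
    return mo.Morphology(
        region=np.array([int(Region.SOMA)]),
        xyz=np.zeros((1, 3)),
        radius=np.array([radius]),
        parent=np.array([-1]),
    )


@pytest.fixture(scope="session")
def family_results():
    """Gain cutoff + onset rapidity across the {1, 5, 10, 15} mm family."""
    return ex.dendritic_length_family(
        tdls=FAMILY_TDLS,
        seed=FAMILY_SEED,
        seconds_per_freq=FAMILY_SECONDS_PER_FREQ,
        onset_duration=5.0,
    )


@pytest.fixture(scope="session")
def contrast_results():
    """Calibrated gain experiments for the 1 mm and 15 mm reference models.

    Calibration runs with backward Euler at 25 µs; the sweep itself with
    Crank-Nicolson at the reference 10 µs step (first-order damping at a
    coarser step measurably blunts phase locking near the cutoff).
    """
    out = {}
    for tdl in (1000.0, 15000.0):
        model = ex.build_model_neuron(tdl)
        out[tdl] = ex.run_gain_experiment(
            model,
            seed=FAMILY_SEED,
            probe_frequencies=CONTRAST_PROBES,
            seconds_per_freq=CONTRAST_SECONDS,
            dt=2.5e-5,
            sweep_dt=1e-5,
            sweep_theta=0.5,
            tdl=tdl,
        )
    return out


@pytest.fixture(scope="session")
def small_tree_model():
    """Cheap assigned model (2 mm arbor) for solver-level tests."""
    return ex.build_model_neuron(2000.0, seed=3)
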