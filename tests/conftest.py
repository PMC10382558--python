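"""Shared fixtures: reference parameter sets and seeded synthetic traces."""

import numpy as np
import pytest

from kirgate import AcquisitionParams, ModelParams
from kirgate.gating_simulator import simulate_occupancy_trace

# G178D reference values used as simulation ground truths throughout:
# four sub-state amplitudes relative to the ~60 pS full level, and their
# pH 7.4 time-weighted probabilities (closed takes the remainder).
REL_AMPLITUDES = np.array([0.45, 0.74, 0.92, 1.00])
SUBSTATE_PROBS = {"O4": 0.59, "O3": 0.26, "O2": 0.07, "O1": 0.02}
FULL_CONDUCTANCE_PS = 60.0
VOLTAGE_MV = -120.0

LEVELS_WITH_CLOSED = np.concatenate([[0.0], REL_AMPLITUDES])
OCC_WITH_CLOSED = np.array([1.0 - sum(SUBSTATE_PROBS.values()),
                            SUBSTATE_PROBS["O1"], SUBSTATE_PROBS["O2"],
                            SUBSTATE_PROBS["O3"], SUBSTATE_PROBS["O4"]])


@pytest.fixture(scope="session")
def model_params() -> ModelParams:
    """Homotetramer model with the reference equilibrium constants."""
    return ModelParams.single_class(n_sites=4, K_H=2e-7, K_OC=0.05)


@pytest.fixture(scope="session")
def benchmark_trace():
    """60 s seeded 4-sub-state trace with realistic noise (ground truth on)."""
    acq = AcquisitionParams(noise_sd=0.3, voltage=VOLTAGE_MV,
                            full_conductance=FULL_CONDUCTANCE_PS, seed=42)
    return simulate_occupancy_trace(LEVELS_WITH_CLOSED, OCC_WITH_CLOSED,
                                    acq, duration=60.0, seed=42)
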