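import numpy as np
import pytest

from myelosim import SurvivalCurve, simulate_sequence
from myelosim.engine import LineModel, SimulationSettings
from myelosim.fixtures import (
    calibrate_exponential_library,
    calibration_targets,
)
from myelosim.outcomes import sequence_outcomes


@pytest.fixture(scope="session")
def calibrated_outcomes():
    """Outcomes for all five shipped sequences, calibrated at attrition 0.7."""
    settings = SimulationSettings()
    out = {}
    for target in calibration_targets(0.7):
        models = calibrate_exponential_library(target, settings)
        trace = simulate_sequence(models, settings)
        out[target.label] = sequence_outcomes(trace, label=target.label)
    return out


def random_exponential_models(rng, n_lines=None, final_attrition=0.0):
    """Random exponential line models for mass-balance property tests."""
    if n_lines is None:
        n_lines = int(rng.integers(1, 5))
    models = []
    for k in range(n_lines):
        rate = float(rng.uniform(0.2, 3.0))
        attrition = float(rng.uniform(0.0, 1.0)) if k < n_lines - 1 else final_attrition
        models.append(
            LineModel(
                regimen=f"L{k + 1}",
                pfs_curve=SurvivalCurve("exponential", (rate,)),
                attrition=attrition,
            )
        )
    return models


def oracle_os(conditional_means, attritions):
    """Closed-form OS for exponential lines: sum of entry prob x conditional mean."""
    total, entry = 0.0, 1.0
    for k, c in enumerate(conditional_means):
        total += entry * c
        if k < len(attritions):
            entry *= attritions[k]
    return total
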