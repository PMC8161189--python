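"""Shared fixtures.

Expensive simulations (the calibration arms, steady-state trough runs and the
synthetic cohorts) are session-scoped so every test module reuses one run.
Cohort sizes are reduced relative to the clinical dataset (fewer patients,
cached noise-free troughs) to keep the suite fast; observation counts match.
"""

from __future__ import annotations

import numpy as np
import pytest

from cyclopbpk import (
    CyclosporinePBPK,
    Demographics,
    SyntheticCohortSpec,
    build_reference_individual,
    generate_cohort,
    load_cyclosporine,
)
from cyclopbpk.engine import SolverOptions

#: relaxed tolerances for bulk cohort generation (trough changes < 0.1 %)
FAST_SOLVER = SolverOptions(rtol=1e-6, atol=1e-8)

PATIENT_28 = Demographics(sex="male", age_years=41, body_weight_kg=77,
                          body_height_cm=180)


@pytest.fixture(scope="session")
def compound():
    return load_cyclosporine()


@pytest.fixture(scope="session")
def reference_individual():
    return build_reference_individual()


@pytest.fixture(scope="session")
def reference_model(compound):
    return CyclosporinePBPK.reference(compound)


@pytest.fixture(scope="session")
def iv_reference_run(reference_model):
    """1.5 mg/kg x 73 kg infusion over 3 h, simulated over the 24 h study window."""
    return reference_model.simulate_iv(1.5 * 73.0, 3.0, t_end_h=24.0)


@pytest.fixture(scope="session")
def oral_100_run(reference_model):
    return reference_model.simulate_oral(100.0, t_end_h=24.0)


@pytest.fixture(scope="session")
def oral_600_run(reference_model):
    return reference_model.simulate_oral(600.0, t_end_h=24.0)


@pytest.fixture(scope="session")
def patient28_trough(compound):
    return CyclosporinePBPK.for_patient(PATIENT_28, compound).predict_trough(62.5)


@pytest.fixture(scope="session")
def calibration_table(compound):
    from cyclopbpk import run_calibration_suite

    return run_calibration_suite(compound)


@pytest.fixture(scope="session")
def zero_noise_cohort(compound):
    spec = SyntheticCohortSpec(n_patients=3, n_observations_total=24,
                               obs_per_patient_range=(4, 10),
                               n_dose_changes_range=(1, 2),
                               log10_noise_sd=0.0, patient_offset_sd=0.0, seed=11)
    return generate_cohort(spec, compound, solver=FAST_SOLVER)


@pytest.fixture(scope="session")
def noisy_cohort(compound):
    """356 observations at the fold-agreement-calibrated noise SD (reduced patients)."""
    spec = SyntheticCohortSpec(n_patients=6, n_observations_total=356,
                               obs_per_patient_range=(40, 80),
                               n_dose_changes_range=(1, 3),
                               log10_noise_sd=0.204, patient_offset_sd=0.0, seed=7)
    return generate_cohort(spec, compound, solver=FAST_SOLVER)


@pytest.fixture(scope="session")
def recovery_cohort(compound):
    """Large-n cohort (1000 observations) for noise-SD recovery."""
    spec = SyntheticCohortSpec(n_patients=5, n_observations_total=1000,
                               obs_per_patient_range=(100, 300),
                               n_dose_changes_range=(1, 3),
                               log10_noise_sd=0.15, patient_offset_sd=0.0, seed=23)
    return generate_cohort(spec, compound, solver=FAST_SOLVER)


def auc_of(run) -> float:
    p = run.profile
    return float(np.trapezoid(p.conc_ng_ml, p.time_h))
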