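"""Synthetic therapeutic-drug-monitoring cohorts.

The clinical trough dataset the model was evaluated against (32 renal
transplant outpatients, 356 trough levels, q12h doses of 25–225 mg, 1–11
different doses per patient) is unpublished.  This module generates cohorts
with the same structure so the comparison pipeline is fully testable:
biometrics sampled from the cohort's ranges, heights imputed, noise-free
"true" troughs computed by the PBPK model, and observations produced by
multiplicative base-10 lognormal noise with an optional between-patient
offset mimicking patient-clustered residua.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .compound import CompoundModel, load_cyclosporine
from .physiology import Demographics, impute_height
from .simulation import DEFAULT_SOLVER, predict_trough
from .tdm import MatchedPair

__all__ = [
    "SyntheticCohortSpec",
    "SyntheticCohort",
    "generate_cohort",
    "calibrate_noise_to_fold_agreement",
]

TWOFOLD_LOG10 = float(np.log10(2.0))


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Structure of a synthetic TDM cohort; defaults mirror the clinical cohort."""

    n_patients: int = 32
    sex_ratio_male: float = 0.5
    age_range_years: tuple = (22, 66)
    bw_range_kg: tuple = (48, 111)
    dose_range_mg: tuple = (25.0, 225.0)
    dose_step_mg: float = 12.5
    n_dose_changes_range: tuple = (1, 11)
    obs_per_patient_range: tuple = (2, 22)
    n_observations_total: int | None = 356
    log10_noise_sd: float = 0.204
    patient_offset_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("age_range_years", "bw_range_kg", "dose_range_mg",
                     "n_dose_changes_range", "obs_per_patient_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered")
        if self.log10_noise_sd < 0 or self.patient_offset_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if not 0 <= self.sex_ratio_male <= 1:
            raise ValueError("sex ratio must lie in [0, 1]")


@dataclass
class SyntheticCohort:
    spec: SyntheticCohortSpec
    patients: pd.DataFrame       # patient_id, sex, age_years, body_weight_kg, body_height_cm
    observations: pd.DataFrame   # patient_id, dose_mg, c0_obs
    truth: pd.DataFrame          # patient_id, dose_mg, c0_true

    def matched_pairs(self) -> list:
        """Pairs of (noise-free prediction, noisy observation) for the pipeline."""
        merged = self.observations.merge(self.truth, on=["patient_id", "dose_mg"])
        merged = merged.merge(self.patients[["patient_id", "body_weight_kg"]], on="patient_id")
        return [
            MatchedPair(patient_id=str(r.patient_id), dose_mg=float(r.dose_mg),
                        bw_dose_mg_kg=float(r.dose_mg / r.body_weight_kg),
                        c0_pred=float(r.c0_true), c0_obs=float(r.c0_obs))
            for r in merged.itertuples()
        ]


def _truncated_geometric(rng: np.random.Generator, lo: int, hi: int, p: float = 0.4) -> int:
    """Dose-change counts are strongly right-skewed (median 2 within 1–11)."""
    while True:
        k = lo + rng.geometric(p) - 1
        if k <= hi:
            return int(k)


def generate_cohort(spec: SyntheticCohortSpec,
                    compound: CompoundModel | None = None,
                    solver=DEFAULT_SOLVER) -> SyntheticCohort:
    """Generate a reproducible synthetic cohort.

    For every (patient, dose) the noise-free truth is the PBPK steady-state
    trough; each observation is truth · 10^(δ_patient + ε) with
    δ_patient ~ N(0, patient_offset_sd²) and ε ~ N(0, log10_noise_sd²).
    Troughs are cached per (patient, dose), so repeated observations of the
    same pair cost one simulation.
    """
    rng = np.random.default_rng(spec.seed)
    compound = compound or load_cyclosporine()

    n_male = int(round(spec.n_patients * spec.sex_ratio_male))
    sexes = ["male"] * n_male + ["female"] * (spec.n_patients - n_male)
    rng.shuffle(sexes)

    patients = []
    for i, sex in enumerate(sexes, start=1):
        age = int(rng.integers(spec.age_range_years[0], spec.age_range_years[1] + 1))
        bw = float(np.round(rng.uniform(*spec.bw_range_kg), 1))
        patients.append({
            "patient_id": f"S{i:02d}", "sex": sex, "age_years": age,
            "body_weight_kg": bw, "body_height_cm": impute_height(sex, age),
        })
    patients = pd.DataFrame(patients)

    dose_grid = np.arange(spec.dose_range_mg[0], spec.dose_range_mg[1] + 1e-9,
                          spec.dose_step_mg)
    per_patient_doses: dict[str, np.ndarray] = {}
    obs_counts: dict[str, int] = {}
    for row in patients.itertuples():
        k = _truncated_geometric(rng, *spec.n_dose_changes_range)
        per_patient_doses[row.patient_id] = rng.choice(dose_grid, size=min(k, len(dose_grid)),
                                                       replace=False)
        obs_counts[row.patient_id] = int(rng.integers(spec.obs_per_patient_range[0],
                                                      spec.obs_per_patient_range[1] + 1))

    # draw the observation skeleton, then trim/pad to the requested total
    skeleton = []
    for row in patients.itertuples():
        doses = per_patient_doses[row.patient_id]
        for _ in range(obs_counts[row.patient_id]):
            skeleton.append((row.patient_id, float(rng.choice(doses))))
    if spec.n_observations_total is not None:
        while len(skeleton) < spec.n_observations_total:
            row = patients.iloc[int(rng.integers(len(patients)))]
            skeleton.append((row.patient_id,
                             float(rng.choice(per_patient_doses[row.patient_id]))))
        if len(skeleton) > spec.n_observations_total:
            keep = rng.choice(len(skeleton), size=spec.n_observations_total, replace=False)
            skeleton = [skeleton[i] for i in sorted(keep)]

    offsets = {row.patient_id: rng.normal(0.0, spec.patient_offset_sd)
               if spec.patient_offset_sd > 0 else 0.0
               for row in patients.itertuples()}

    trough_cache: dict[tuple, float] = {}
    pt_by_id = {row.patient_id: row for row in patients.itertuples()}

    def truth_for(pid: str, dose: float) -> float:
        key = (pid, dose)
        if key not in trough_cache:
            r = pt_by_id[pid]
            demo = Demographics(sex=r.sex, age_years=r.age_years,
                                body_weight_kg=r.body_weight_kg,
                                body_height_cm=r.body_height_cm)
            trough_cache[key] = predict_trough(demo, dose, compound, solver=solver)
        return trough_cache[key]

    obs_rows = []
    for pid, dose in skeleton:
        c0_true = truth_for(pid, dose)
        eps = rng.normal(0.0, spec.log10_noise_sd) if spec.log10_noise_sd > 0 else 0.0
        c0_obs = c0_true * 10.0 ** (offsets[pid] + eps)
        obs_rows.append({"patient_id": pid, "dose_mg": dose, "c0_obs": c0_obs})

    truth = pd.DataFrame([{"patient_id": pid, "dose_mg": dose, "c0_true": v}
                          for (pid, dose), v in sorted(trough_cache.items())])
    return SyntheticCohort(spec=spec, patients=patients,
                           observations=pd.DataFrame(obs_rows), truth=truth)


def calibrate_noise_to_fold_agreement(target_frac_2fold: float) -> float:
    """Log10 noise SD whose lognormal error gives the target within-twofold fraction.

    Inverts P(|ε| < log10 2) = target for ε ~ N(0, sd²):
    sd = log10(2) / z_{(1+target)/2}.  A target of 0.86 gives sd ≈ 0.204.
    """
    if not 0 < target_frac_2fold < 1:
        raise ValueError("target fraction must lie strictly between 0 and 1")
    z = norm.ppf((1.0 + target_frac_2fold) / 2.0)
    return float(TWOFOLD_LOG10 / z)
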