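"""Virtual-individual anatomy and physiology.

Builds the organ volume / blood-flow / tissue-composition table for a virtual
adult from demographics (sex, age, body weight, body height).  The reference
individual is an average European male (30 y, 73 kg, 176 cm).  Organ volumes of
lean tissues scale with lean body weight (Boer formula); adipose tissue absorbs
the remaining body mass so that total tissue volume equals body weight divided
by a mean body density of 1.05 kg/L.  Regional blood flows scale with cardiac
output, taken proportional to BW^0.75 with a mild linear decline with age.

Body height, when missing from a patient record, is imputed from an embedded
sex-by-age-band table of German population average heights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Demographics",
    "GIGeometry",
    "VirtualIndividual",
    "build_individual",
    "build_reference_individual",
    "impute_height",
    "BODY_DENSITY_KG_L",
    "REFERENCE_DEMOGRAPHICS",
]

BODY_DENSITY_KG_L = 1.05

#: organs perfused in the systemic circulation vs. draining into the portal vein
SYSTEMIC_ORGANS = ("heart", "bone", "skin", "kidney", "muscle", "brain", "adipose")
PORTAL_ORGANS = ("spleen", "stomach", "small_intestine", "colon")

#: intestinal mucosa compartments (permeability-limited; no convective flow entry)
GUT_SEGMENTS = (
    "duodenum",
    "upper_jejunum",
    "lower_jejunum",
    "upper_ileum",
    "lower_ileum",
    "colon",
)
LUMEN_SEGMENTS = ("stomach",) + GUT_SEGMENTS


@dataclass(frozen=True)
class Demographics:
    """Patient biometrics; height is optional and may be imputed."""

    sex: str  # "male" | "female"
    age_years: float
    body_weight_kg: float
    body_height_cm: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not self.age_years > 0:
            raise ValueError("age must be positive")
        if not self.body_weight_kg > 0:
            raise ValueError("body weight must be positive")
        if self.body_height_cm is not None and not (100 < self.body_height_cm < 230):
            raise ValueError("body height must lie in (100, 230) cm")


REFERENCE_DEMOGRAPHICS = Demographics(
    sex="male", age_years=30.0, body_weight_kg=73.0, body_height_cm=176.0
)

# Reference organ table for the 73 kg adult male.  Volumes (L), regional blood
# flows (L/min) and tissue composition (mass fractions of water, neutral lipid
# and protein) follow reference-human compilations used by whole-body PBPK
# platforms.  Mucosa rows carry no convective flow (permeability-limited).
_REF_COLUMNS = ("volume_l", "flow_l_min", "f_water", "f_lipid", "f_protein")
_REF_CO_L_MIN = 5.6
_REF_ROWS = {
    # organ:            V (L)   Q (L/min)  f_w    f_l    f_p
    "lung":            (0.55,   _REF_CO_L_MIN, 0.79, 0.02, 0.19),
    "heart":           (0.33,   0.224,     0.73,  0.10,  0.17),
    "bone":            (10.0,   0.280,     0.40,  0.25,  0.35),
    "skin":            (3.30,   0.280,     0.65,  0.10,  0.25),
    "kidney":          (0.31,   1.064,     0.77,  0.05,  0.18),
    "spleen":          (0.15,   0.168,     0.78,  0.03,  0.19),
    "liver":           (1.80,   0.364,     0.72,  0.07,  0.21),
    "stomach":         (0.15,   0.056,     0.75,  0.06,  0.19),
    "small_intestine": (0.455,  0.560,     0.75,  0.06,  0.19),
    "colon":           (0.31,   0.224,     0.75,  0.06,  0.19),
    "muscle":          (29.0,   0.952,     0.76,  0.04,  0.20),
    "brain":           (1.45,   0.672,     0.77,  0.11,  0.12),
    "adipose":         (15.0,   0.280,     0.15,  0.80,  0.05),
    "mucosa_duodenum":      (0.015, 0.0, 0.75, 0.06, 0.19),
    "mucosa_upper_jejunum": (0.045, 0.0, 0.75, 0.06, 0.19),
    "mucosa_lower_jejunum": (0.045, 0.0, 0.75, 0.06, 0.19),
    "mucosa_upper_ileum":   (0.040, 0.0, 0.75, 0.06, 0.19),
    "mucosa_lower_ileum":   (0.040, 0.0, 0.75, 0.06, 0.19),
    "mucosa_colon":         (0.060, 0.0, 0.75, 0.06, 0.19),
    "blood_arterial":  (1.40,   _REF_CO_L_MIN, 0.93, 0.007, 0.06),
    "blood_venous":    (3.90,   _REF_CO_L_MIN, 0.93, 0.007, 0.06),
}


def _reference_table() -> pd.DataFrame:
    return pd.DataFrame.from_dict(_REF_ROWS, orient="index", columns=list(_REF_COLUMNS))


# German population average body height (cm) by sex and age band, recovered from
# the clinical cohort's imputed values (federal micro-census averages).
_HEIGHT_BANDS = {
    "male": ((18, 30, 181.0), (30, 50, 180.0), (50, 55, 179.0), (55, 65, 178.0), (65, 90, 176.0)),
    "female": ((18, 30, 168.0), (30, 50, 167.0), (50, 55, 166.0), (55, 60, 165.0), (60, 90, 164.0)),
}


def impute_height(sex: str, age_years: float) -> float:
    """German average body height (cm) for the given sex and age band.

    Raises ``ValueError`` outside the supported adult age range (18, 90).
    """
    if sex not in _HEIGHT_BANDS:
        raise ValueError(f"unknown sex {sex!r}")
    if not (18 < age_years < 90):
        raise ValueError(f"height imputation unsupported for age {age_years}")
    for lo, hi, height in _HEIGHT_BANDS[sex]:
        if lo <= age_years < hi:
            return height
    raise ValueError(f"height imputation unsupported for age {age_years}")


@dataclass(frozen=True)
class GIGeometry:
    """Luminal geometry of the gastrointestinal tract (adult defaults).

    ``fluid_volume_l``  free luminal fluid per segment (dose taken with water),
    ``surface_cm2``     smooth cylindrical surface per absorbing segment,
    ``transit_k_per_min`` first-order transit rate constants.
    The smooth surface is multiplied by the compound file's effective surface
    enlargement (folds/villi/microvilli) before computing absorptive flux.
    """

    fluid_volume_l: dict = field(default_factory=lambda: {
        "stomach": 0.30, "duodenum": 0.05, "upper_jejunum": 0.08,
        "lower_jejunum": 0.08, "upper_ileum": 0.07, "lower_ileum": 0.07,
        "colon": 0.15,
    })
    surface_cm2: dict = field(default_factory=lambda: {
        # 2*pi*r*L with lengths 25/105/105/105/105/150 cm, radii tapering 1.6->1.1, colon 2.5
        "duodenum": 251.0, "upper_jejunum": 924.0, "lower_jejunum": 858.0,
        "upper_ileum": 792.0, "lower_ileum": 726.0, "colon": 2356.0,
    })
    transit_k_per_min: dict = field(default_factory=lambda: {
        # gastric emptying t1/2 ~ 12 min; small-intestinal transit ~ 3.3 h over
        # five segments; colonic residence ~ 23 h
        "stomach": 0.058, "duodenum": 0.025, "upper_jejunum": 0.025,
        "lower_jejunum": 0.025, "upper_ileum": 0.025, "lower_ileum": 0.025,
        "colon": 1.0 / 1400.0,
    })


@dataclass(frozen=True)
class VirtualIndividual:
    demographics: Demographics
    organs: pd.DataFrame  # indexed by organ, columns _REF_COLUMNS
    hematocrit: float
    gi: GIGeometry = field(default_factory=GIGeometry)

    def __post_init__(self) -> None:
        if not (0.3 < self.hematocrit < 0.6):
            raise ValueError("hematocrit outside plausible range (0.3, 0.6)")
        v = self.organs["volume_l"]
        if (v <= 0).any() or (self.organs["flow_l_min"] < 0).any():
            raise ValueError("organ volumes must be positive and flows non-negative")

    @property
    def total_volume_l(self) -> float:
        return float(self.organs["volume_l"].sum())

    @property
    def cardiac_output_l_min(self) -> float:
        return float(self.organs.loc["lung", "flow_l_min"])


def _lean_body_weight_kg(demo: Demographics) -> float:
    """Boer lean body weight."""
    w, h = demo.body_weight_kg, demo.body_height_cm
    if demo.sex == "male":
        return 0.407 * w + 0.267 * h - 19.2
    return 0.252 * w + 0.473 * h - 48.3


_REF_LBW = _lean_body_weight_kg(REFERENCE_DEMOGRAPHICS)


def build_reference_individual() -> VirtualIndividual:
    """The calibration individual: male, 30 y, 73 kg, 176 cm."""
    return VirtualIndividual(
        demographics=REFERENCE_DEMOGRAPHICS,
        organs=_reference_table(),
        hematocrit=0.45,
    )


def build_individual(demographics: Demographics) -> VirtualIndividual:
    """Scale the reference organ table to an individual's demographics.

    Lean organs (everything except adipose) and blood scale with the ratio of
    lean body weights; adipose volume takes up the residual so that total
    volume equals BW / 1.05 kg/L exactly.  Flows scale with cardiac output
    ~ BW^0.75 with a 0.4 %/year decline past age 30.
    """
    demo = demographics
    if demo.body_height_cm is None:
        demo = replace(demo, body_height_cm=impute_height(demo.sex, demo.age_years))
    if demo == REFERENCE_DEMOGRAPHICS:
        return build_reference_individual()

    table = _reference_table()
    lean_factor = max(_lean_body_weight_kg(demo) / _REF_LBW, 0.3)
    lean = table.index != "adipose"
    table.loc[lean, "volume_l"] *= lean_factor
    target_total = demo.body_weight_kg / BODY_DENSITY_KG_L
    adipose = target_total - float(table.loc[lean, "volume_l"].sum())
    min_adipose = 0.02 * _REF_ROWS["adipose"][0]
    table.loc["adipose", "volume_l"] = max(adipose, min_adipose)

    age_factor = float(np.clip(1.0 - 0.004 * (demo.age_years - 30.0), 0.75, 1.08))
    co_factor = (demo.body_weight_kg / 73.0) ** 0.75 * age_factor
    table["flow_l_min"] *= co_factor

    hct = 0.45 if demo.sex == "male" else 0.40
    return VirtualIndividual(demographics=demo, organs=table, hematocrit=hct)
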