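"""Cyclosporine compound parameterization.

Loads the bundled compound file (physico-chemistry, plasma binding, nine
saturable binding sites, CYP3A4 metabolism, P-gp efflux) with the published
units, converts everything to the internal unit system (µmol, L, min) and
derives the passive tissue-to-plasma partition coefficients from tissue
composition.

The binding sites deliberately keep their mixed dissociation-rate units
(per second for lung/heart/bone/skin/blood cells, per hour for kidney/
spleen/liver/intestine): the per-second sites equilibrate within seconds
(fast pools) while the per-hour sites act as slowly filling reservoirs.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "PhysChem",
    "BindingSite",
    "MetabolismCYP3A4",
    "EffluxPGP",
    "PlasmaBinding",
    "PlatformParams",
    "CompoundModel",
    "load_cyclosporine",
    "association_rate",
    "compute_partition_coefficients",
]

FAST_KOFF_UNIT = "per_s"
SLOW_KOFF_UNIT = "per_h"


@dataclass(frozen=True)
class PhysChem:
    molecular_weight_g_mol: float
    charge_class: str
    log_p: float
    solubility_ug_ml: float
    intestinal_permeability_cm_min: float

    def __post_init__(self):
        for name in ("molecular_weight_g_mol", "solubility_ug_ml",
                     "intestinal_permeability_cm_min"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def solubility_umol_l(self) -> float:
        # µg/ml == mg/L; / (g/mol) -> mmol/L -> µmol/L
        return self.solubility_ug_ml / self.molecular_weight_g_mol * 1000.0


@dataclass(frozen=True)
class BindingSite:
    """Saturable binding pool: K_M (µmol/L), K_OFF (declared unit), B_C (µmol/L)."""

    tissue: str
    k_m_umol_l: float
    k_off: float
    k_off_unit: str
    b_c_umol_l: float

    def __post_init__(self):
        if self.k_off_unit not in (FAST_KOFF_UNIT, SLOW_KOFF_UNIT):
            raise ValueError(f"unknown k_off unit {self.k_off_unit!r}")
        if min(self.k_m_umol_l, self.k_off, self.b_c_umol_l) <= 0:
            raise ValueError("binding-site parameters must be positive")

    @property
    def k_off_per_min(self) -> float:
        return self.k_off * 60.0 if self.k_off_unit == FAST_KOFF_UNIT else self.k_off / 60.0

    @property
    def is_fast(self) -> bool:
        return self.k_off_unit == FAST_KOFF_UNIT


def association_rate(site: BindingSite) -> float:
    """Mass-action association rate k_on = K_OFF / K_M, per (µmol/L)·min.

    Closes the published (K_M, K_OFF) pairs so that the pool equilibrium is
    the saturable isotherm B_C·C/(K_M + C).
    """
    if site.k_m_umol_l <= 0:
        raise ValueError("k_m must be positive")
    return site.k_off_per_min / site.k_m_umol_l


@dataclass(frozen=True)
class MetabolismCYP3A4:
    k_m_nmol_ml: float                      # == µmol/L
    v_max_nmol_min_g: float
    b_c_liver_umol_l: float
    relative_abundance: dict                # organ -> fraction of liver activity
    cl_ii_l_h: float                        # intestinal intrinsic clearance
    b_c_by_segment_umol_l: dict             # duodenum .. lower_ileum

    def __post_init__(self):
        bad = {k: v for k, v in self.relative_abundance.items() if not 0 <= v <= 1}
        if bad:
            raise ValueError(f"relative abundances outside [0, 1]: {bad}")
        required = {"duodenum", "upper_jejunum", "lower_jejunum", "upper_ileum", "lower_ileum"}
        if set(self.b_c_by_segment_umol_l) != required:
            raise ValueError("intestinal B_C must cover duodenum through lower ileum")

    @property
    def cl_ii_l_min(self) -> float:
        return self.cl_ii_l_h / 60.0

    def segment_weights(self) -> dict:
        """Cl_II split over small-intestinal segments, proportional to segmental B_C."""
        total = sum(self.b_c_by_segment_umol_l.values())
        return {s: b / total for s, b in self.b_c_by_segment_umol_l.items()}


@dataclass(frozen=True)
class EffluxPGP:
    k_m_umol_l: float
    v_max_nmol_ml_min: float
    b_c_colon_umol_l: float
    brain_b_c_umol_l: float
    intestinal_relative_distribution: dict  # ileum/jejunum/duodenum fractions + colon baseline

    def __post_init__(self):
        si = sum(v for k, v in self.intestinal_relative_distribution.items() if k != "colon")
        if abs(si - 1.0) > 1e-9:
            raise ValueError("small-intestinal P-gp distribution fractions must sum to 1")

    def segment_capacity(self) -> dict:
        """Relative P-gp capacity per mucosal segment (colon carries the baseline B_C).

        Paired small-intestinal segments (upper/lower jejunum, upper/lower
        ileum) split their region's fraction equally.
        """
        d = self.intestinal_relative_distribution
        return {
            "duodenum": d["duodenum"],
            "upper_jejunum": d["jejunum"] / 2.0,
            "lower_jejunum": d["jejunum"] / 2.0,
            "upper_ileum": d["ileum"] / 2.0,
            "lower_ileum": d["ileum"] / 2.0,
            "colon": d["colon"] * self.b_c_colon_umol_l,
        }


@dataclass(frozen=True)
class PlasmaBinding:
    fraction_unbound: float

    def __post_init__(self):
        if not 0 < self.fraction_unbound <= 1:
            raise ValueError("fraction unbound must lie in (0, 1]")


@dataclass(frozen=True)
class PlatformParams:
    """Anatomy/absorption-platform parameters not fixed by the compound table.

    Calibrated once against the healthy-volunteer IV and oral study arms and
    stored in the compound file.
    """

    partition_scalar: float
    basolateral_clearance_l_h: float
    surface_enlargement_small_intestine: float
    surface_enlargement_colon: float
    tissue_permeability_l_min_per_l: float = float("inf")
    brain_efflux_enabled: bool = True

    @property
    def basolateral_clearance_l_min(self) -> float:
        return self.basolateral_clearance_l_h / 60.0


@dataclass(frozen=True)
class CompoundModel:
    name: str
    phys_chem: PhysChem
    plasma_binding: PlasmaBinding
    binding_sites: tuple
    metabolism: MetabolismCYP3A4
    efflux: EffluxPGP
    platform: PlatformParams
    raw: dict = field(repr=False, default_factory=dict)

    def __post_init__(self):
        if len(self.binding_sites) != 9:
            raise ValueError(f"expected 9 binding sites, got {len(self.binding_sites)}")

    def site(self, tissue: str) -> BindingSite:
        for s in self.binding_sites:
            if s.tissue == tissue:
                return s
        raise KeyError(tissue)

    def to_dict(self) -> dict:
        return self.raw

    @classmethod
    def from_dict(cls, cfg: dict) -> "CompoundModel":
        try:
            pc = PhysChem(**cfg["phys_chem"])
            pb = PlasmaBinding(**cfg["plasma_binding"])
            sites = tuple(BindingSite(**s) for s in cfg["binding_sites"])
            met_cfg = cfg["metabolism"]
            met = MetabolismCYP3A4(
                k_m_nmol_ml=met_cfg["systemic"]["k_m_nmol_ml"],
                v_max_nmol_min_g=met_cfg["systemic"]["v_max_nmol_min_g"],
                b_c_liver_umol_l=met_cfg["systemic"]["b_c_liver_umol_l"],
                relative_abundance=dict(met_cfg["systemic"]["relative_abundance"]),
                cl_ii_l_h=met_cfg["intestinal"]["cl_ii_l_h"],
                b_c_by_segment_umol_l=dict(met_cfg["intestinal"]["b_c_by_segment_umol_l"]),
            )
            eff = EffluxPGP(
                k_m_umol_l=cfg["efflux"]["k_m_umol_l"],
                v_max_nmol_ml_min=cfg["efflux"]["v_max_nmol_ml_min"],
                b_c_colon_umol_l=cfg["efflux"]["b_c_colon_umol_l"],
                brain_b_c_umol_l=cfg["efflux"]["brain_b_c_umol_l"],
                intestinal_relative_distribution=dict(
                    cfg["efflux"]["intestinal_relative_distribution"]
                ),
            )
            plat = PlatformParams(**cfg["platform"])
        except (KeyError, TypeError) as exc:
            raise ValueError(f"invalid compound file: {exc}") from exc
        return cls(
            name=cfg.get("name", "unnamed"),
            phys_chem=pc, plasma_binding=pb, binding_sites=sites,
            metabolism=met, efflux=eff, platform=plat, raw=cfg,
        )

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.raw, sort_keys=False))


def _bundled_path() -> Path:
    return Path(importlib.resources.files("cyclopbpk").joinpath("data/cyclosporine.yaml"))


def load_cyclosporine(path: str | Path | None = None,
                      overrides: dict | None = None) -> CompoundModel:
    """Load the bundled cyclosporine compound file (or a user-edited copy).

    ``overrides`` maps dotted config paths (e.g. ``"plasma_binding.fraction_unbound"``)
    to replacement values; used by the sensitivity analysis.
    """
    cfg = yaml.safe_load(Path(path or _bundled_path()).read_text())
    if overrides:
        for dotted, value in overrides.items():
            node = cfg
            *parents, leaf = dotted.split(".")
            for key in parents:
                node = node[key]
            if leaf not in node:
                raise KeyError(f"unknown compound parameter {dotted!r}")
            node[leaf] = value
    return CompoundModel.from_dict(cfg)


def compute_partition_coefficients(phys_chem: PhysChem,
                                   plasma_binding: PlasmaBinding,
                                   organs: pd.DataFrame,
                                   partition_scalar: float = 1.0) -> dict:
    """Passive tissue:plasma partition coefficients from tissue composition.

    Tissue affinity is modelled as water + membrane-lipid affinity,
    ``a_t = f_water + s·10^logP·f_lipid``; with unbound plasma drug in
    equilibrium with tissue water, ``Kp = fu_plasma · a_t``.  The global
    scalar ``s`` absorbs the difference between octanol and membrane
    lipids and is calibrated once against the IV profiles.
    """
    p_eff = partition_scalar * 10.0 ** phys_chem.log_p
    fu = plasma_binding.fraction_unbound
    kp = {}
    for organ, row in organs.iterrows():
        if organ.startswith("blood"):
            continue
        kp[organ] = fu * (row["f_water"] + p_eff * row["f_lipid"])
    return kp
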