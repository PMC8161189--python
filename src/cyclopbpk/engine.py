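"""Whole-body PBPK ODE system for cyclosporine.

The model couples

* distribution into thirteen perfused organs with composition-derived
  partition coefficients — flow-limited for sinusoidal/fenestrated beds,
  with an additional transcapillary permeation limit for organs with
  continuous capillaries (the drug is a 1203 Da cyclic peptide),
* nine saturable tissue/blood-cell binding pools — the per-second sites
  (lung, heart, bone, skin, blood cells) are kept at local equilibrium inside
  the compartment amounts (they relax within seconds), while the per-hour
  sites (kidney, spleen, liver, intestine) are explicit kinetic states,
* Michaelis–Menten CYP3A4 metabolism distributed over liver, gut, stomach,
  kidney, muscle and brain, driven by the unbound tissue concentration,
* a segmented gastrointestinal tract (stomach plus five small-intestinal
  segments plus colon): first-order luminal transit, passive absorption
  limited by a 190 µg/ml solubility ceiling with instantaneous
  precipitation/redissolution, a permeability-limited mucosa with intrinsic
  CYP3A4 clearance (Cl_II, split over segments by enzyme abundance) and
  saturable P-glycoprotein efflux back into the lumen,
* intravenous constant-rate infusion into venous blood and oral dosing as a
  solution bolus into the stomach lumen.

Internal units are µmol, L and minutes; the public surface reports hours and
ng/ml whole blood.  No renal or biliary excretion of parent drug is modelled:
elimination is exclusively metabolic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .compound import BindingSite, CompoundModel, MetabolismCYP3A4, EffluxPGP, association_rate, \
    compute_partition_coefficients
from .physiology import GUT_SEGMENTS, LUMEN_SEGMENTS, VirtualIndividual

__all__ = [
    "DoseEvent",
    "SolverOptions",
    "EngineIntegrityError",
    "CompiledModel",
    "assemble_rhs",
    "integrate",
    "binding_rate",
    "mm_metabolism_rate",
    "gut_wall_extraction_rate",
    "pgp_efflux_rate",
    "gi_absorption_rate",
    "whole_blood_concentration",
]

ORGANS = (
    "lung", "heart", "bone", "skin", "kidney", "spleen", "liver",
    "stomach", "small_intestine", "colon", "muscle", "brain", "adipose",
)
SYSTEMIC_IDX = (1, 2, 3, 4, 10, 11, 12)       # heart bone skin kidney muscle brain adipose
PORTAL_IDX = (5, 7, 8, 9)                     # spleen stomach small_intestine colon
LUNG, LIVER, BRAIN = 0, 6, 11
N_ORG = len(ORGANS)
ART, VEN = N_ORG, N_ORG + 1                   # 13, 14
MUC0 = VEN + 1                                # 15..20  mucosa per gut segment
LUMD0 = MUC0 + len(GUT_SEGMENTS)              # 21..27  lumen dissolved
LUMS0 = LUMD0 + len(LUMEN_SEGMENTS)           # 28..34  lumen precipitate
SLOW0 = LUMS0 + len(LUMEN_SEGMENTS)           # 35..38  slow binding pools
SLOW_SITES = (("kidney", 4), ("spleen", 5), ("liver", 6), ("intestine", 8))
TRK0 = SLOW0 + len(SLOW_SITES)                # 39..43  cumulative trackers
TRACKERS = ("absorbed_into_gut_wall", "escaped_gut_wall_unmetabolized",
            "metabolized_total", "effluxed_to_lumen", "excreted_unabsorbed",
            "metabolized_hepatic", "mucosa_influx_from_blood")
N_STATE = TRK0 + len(TRACKERS)

_FAST_ORGAN_SITES = {"lung": 0, "heart": 1, "bone": 2, "skin": 3}


class EngineIntegrityError(RuntimeError):
    """Raised when integration produces a non-finite or grossly negative state."""


@dataclass(frozen=True)
class DoseEvent:
    """A single administration: IV constant-rate infusion or oral solution bolus."""

    route: str                       # "iv_infusion" | "oral_solution"
    amount_mg: float
    start_h: float = 0.0
    infusion_duration_h: float | None = None

    def __post_init__(self):
        if self.route not in ("iv_infusion", "oral_solution"):
            raise ValueError(f"unknown route {self.route!r}")
        if self.amount_mg < 0:
            raise ValueError("dose must be non-negative")
        if self.route == "iv_infusion" and not (self.infusion_duration_h or 0) > 0:
            raise ValueError("IV infusion requires a positive duration")


@dataclass(frozen=True)
class SolverOptions:
    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "BDF"


# --- elementary process rates (spec'd operations, concentration/amount basis) ---

def binding_rate(c_unbound: float, bound: float, site: BindingSite) -> float:
    """Net binding rate dBound/dt (µmol/L/min) of a saturable pool.

    ``k_on·C_u·(B_C − bound) − k_off·bound`` with ``k_on = K_OFF/K_M``; the
    stationary point is the isotherm ``B_C·C_u/(K_M + C_u)``.
    """
    if bound > site.b_c_umol_l * (1 + 1e-9) + 1e-12:
        raise EngineIntegrityError(
            f"bound pool {bound} exceeds capacity {site.b_c_umol_l} for {site.tissue}")
    k_on = association_rate(site)
    return k_on * c_unbound * (site.b_c_umol_l - bound) - site.k_off_per_min * bound


def mm_metabolism_rate(c_unbound: float, organ: str, metabolism: MetabolismCYP3A4,
                       organs: pd.DataFrame) -> float:
    """Systemic CYP3A4 rate (µmol/min) in ``organ`` at unbound concentration ``c_unbound``.

    V_MAX is per gram of tissue and scaled by the organ's CYP3A4 abundance
    relative to liver; tissue mass is taken as 1 g/ml of organ volume.
    """
    if organ not in metabolism.relative_abundance:
        raise KeyError(f"no CYP3A4 abundance defined for organ {organ!r}")
    mass_g = float(organs.loc[organ, "volume_l"]) * 1000.0
    vmax = metabolism.v_max_nmol_min_g * 1e-3 * mass_g * metabolism.relative_abundance[organ]
    return vmax * c_unbound / (metabolism.k_m_nmol_ml + c_unbound)


def gut_wall_extraction_rate(c_enterocyte: float, segment: str,
                             metabolism: MetabolismCYP3A4) -> float:
    """First-order gut-wall CYP3A4 clearance rate (µmol/min) in one segment.

    Cl_II is distributed over the small-intestinal segments proportionally to
    the segmental enzyme concentration, so the rates at a uniform mucosal
    concentration sum to Cl_II·c.
    """
    weights = metabolism.segment_weights()
    if segment not in weights:
        raise KeyError(f"no intestinal CYP3A4 in segment {segment!r}")
    return metabolism.cl_ii_l_min * weights[segment] * c_enterocyte


def pgp_efflux_rate(c_unbound: float, compartment: str, efflux: EffluxPGP,
                    volume_l: float) -> float:
    """Saturable P-gp efflux rate (µmol/min) from a gut segment or brain."""
    if compartment == "brain":
        cap = efflux.brain_b_c_umol_l
    else:
        caps = efflux.segment_capacity()
        if compartment not in caps:
            raise KeyError(f"no P-gp distribution for compartment {compartment!r}")
        cap = caps[compartment]
    vmax = efflux.v_max_nmol_ml_min * volume_l  # nmol/ml/min * 1000 ml/L * 1e-3 µmol/nmol
    return vmax * cap * c_unbound / (efflux.k_m_umol_l + c_unbound)


def gi_absorption_rate(luminal_dissolved_umol: float, segment: str,
                       permeability_cm_min: float, surface_cm2: float,
                       fluid_volume_l: float) -> float:
    """Passive absorptive flux (µmol/min) across a segment's effective surface."""
    conc_umol_ml = luminal_dissolved_umol / fluid_volume_l * 1e-3
    return permeability_cm_min * surface_cm2 * conc_umol_ml


# --- compiled model -----------------------------------------------------------

@dataclass
class CompiledModel:
    """Parameter arrays and the RHS for one (individual, compound) pairing."""

    individual: VirtualIndividual
    compound: CompoundModel
    brain_efflux: bool = True
    _arrays: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        ind, cmp_ = self.individual, self.compound
        org = ind.organs
        v = org.loc[list(ORGANS), "volume_l"].to_numpy(float)
        q = org.loc[list(ORGANS), "flow_l_min"].to_numpy(float)
        kp_map = compute_partition_coefficients(
            cmp_.phys_chem, cmp_.plasma_binding, org, cmp_.platform.partition_scalar)
        kp = np.array([kp_map[o] for o in ORGANS])

        fu = cmp_.plasma_binding.fraction_unbound
        hct = ind.hematocrit
        cells = cmp_.site("blood_cells")

        # equilibrium-binding parameters per compartment (organs + art + ven):
        # kappa·Cp + beta·fu·Cp/(km + fu·Cp) = amount/volume
        kappa = np.concatenate([kp, [1.0 - hct, 1.0 - hct]])
        beta = np.zeros(N_ORG + 2)
        km_eq = np.ones(N_ORG + 2)
        for organ, _ in _FAST_ORGAN_SITES.items():
            s = cmp_.site(organ)
            i = ORGANS.index(organ)
            beta[i], km_eq[i] = s.b_c_umol_l, s.k_m_umol_l
        beta[ART] = beta[VEN] = hct * cells.b_c_umol_l   # B_C per litre of cells
        km_eq[ART] = km_eq[VEN] = cells.k_m_umol_l

        # systemic CYP3A4
        met_vmax = np.zeros(N_ORG)
        for organ, rel in cmp_.metabolism.relative_abundance.items():
            met_vmax[ORGANS.index(organ)] = cmp_.metabolism.v_max_nmol_min_g * v[ORGANS.index(organ)] * rel
        km_met = cmp_.metabolism.k_m_nmol_ml

        # slow binding pools
        slow_kon = np.array([association_rate(cmp_.site(t)) for t, _ in SLOW_SITES])
        slow_koff = np.array([cmp_.site(t).k_off_per_min for t, _ in SLOW_SITES])
        slow_cap = np.array([cmp_.site(t).b_c_umol_l * v[i] for t, i in SLOW_SITES])
        slow_org = np.array([i for _, i in SLOW_SITES])

        # mucosa / gut
        vm = org.loc[[f"mucosa_{s}" for s in GUT_SEGMENTS], "volume_l"].to_numpy(float)
        plat = cmp_.platform
        enlarge = np.array([plat.surface_enlargement_small_intestine] * 5
                           + [plat.surface_enlargement_colon])
        area = np.array([ind.gi.surface_cm2[s] for s in GUT_SEGMENTS]) * enlarge
        vf = np.array([ind.gi.fluid_volume_l[s] for s in LUMEN_SEGMENTS])
        kt = np.array([ind.gi.transit_k_per_min[s] for s in LUMEN_SEGMENTS])
        weights = cmp_.metabolism.segment_weights()
        clii = np.array([cmp_.metabolism.cl_ii_l_min * weights.get(s, 0.0) for s in GUT_SEGMENTS])
        pgp_cap = cmp_.efflux.segment_capacity()
        pgp_vmax = np.array([cmp_.efflux.v_max_nmol_ml_min * vm[i] * 1000.0 * 1e-3
                             * pgp_cap[s] for i, s in enumerate(GUT_SEGMENTS)])
        clb = plat.basolateral_clearance_l_min * vm / vm.sum()

        co = q[LUNG]
        q_portal = q[list(PORTAL_IDX)].sum()
        q_shunt = co - (q.sum() - co)        # arterial blood not routed to a named organ
        if q_shunt < 0:
            raise ValueError("regional flows exceed cardiac output")

        # capillary permeation limit: organs with continuous capillaries
        # (heart, bone, skin, muscle, brain, adipose) exchange at
        # Q·PS/(Q+PS) with PS proportional to tissue volume; blood not
        # exchanging with tissue bypasses to the venous pool.  Fenestrated/
        # sinusoidal beds (lung, liver, spleen, kidney, gut) stay flow-limited.
        q_eff = q.copy()
        ps_per_l = plat.tissue_permeability_l_min_per_l
        if np.isfinite(ps_per_l):
            throttled = [ORGANS.index(o) for o in
                         ("heart", "bone", "skin", "muscle", "brain", "adipose")]
            ps = ps_per_l * v[throttled]
            q_eff[throttled] = q[throttled] * ps / (q[throttled] + ps)
        q_bypass = float((q - q_eff)[list(SYSTEMIC_IDX)].sum())

        sol_cap = cmp_.phys_chem.solubility_umol_l * vf

        self._arrays = dict(
            v=v, q=q, kp=kp, fu=fu, hct=hct,
            v_art=float(org.loc["blood_arterial", "volume_l"]),
            v_ven=float(org.loc["blood_venous", "volume_l"]),
            kappa=kappa, beta=beta, km_eq=km_eq,
            cells_bc=hct * cells.b_c_umol_l, cells_km=cells.k_m_umol_l,
            met_vmax=met_vmax, km_met=km_met,
            slow_kon=slow_kon, slow_koff=slow_koff, slow_cap=slow_cap, slow_org=slow_org,
            vm=vm, area=area, vf=vf, kt=kt, clii=clii, pgp_vmax=pgp_vmax,
            pgp_km=cmp_.efflux.k_m_umol_l, clb=clb,
            perm=cmp_.phys_chem.intestinal_permeability_cm_min,
            sol_cap=sol_cap, co=co, q_portal=q_portal, q_shunt=q_shunt,
            q_eff=q_eff, q_bypass=q_bypass,
            brain_pgp_vmax=(cmp_.efflux.v_max_nmol_ml_min * v[BRAIN]
                            * cmp_.efflux.brain_b_c_umol_l
                            if (self.brain_efflux and plat.brain_efflux_enabled) else 0.0),
            mw=cmp_.phys_chem.molecular_weight_g_mol,
            k_precip=1.0,  # 1/min relaxation to the solubility ceiling
        )

    # closed-form inversion of amount/volume -> plasma concentration in a
    # compartment with equilibrium saturable binding
    @staticmethod
    def _plasma_conc(x, kappa, beta, km, fu):
        a = kappa / fu
        b = kappa * km / fu + beta - x
        u = (-b + np.sqrt(b * b + 4.0 * a * x * km)) / (2.0 * a)
        return u / fu

    def _wb(self, cp):
        """Whole-blood concentration in equilibrium with plasma concentration."""
        p = self._arrays
        u = p["fu"] * cp
        return (1.0 - p["hct"]) * cp + p["cells_bc"] * u / (p["cells_km"] + u)

    def whole_blood_ng_ml(self, state: np.ndarray) -> float | np.ndarray:
        """Venous whole-blood concentration (ng/ml) for one state or a trajectory."""
        p = self._arrays
        amt = state[..., VEN]
        return np.maximum(amt, 0.0) / p["v_ven"] * p["mw"]

    def initial_state(self) -> np.ndarray:
        return np.zeros(N_STATE)

    def rhs(self, t: float, y: np.ndarray, iv_rate_umol_min: float = 0.0) -> np.ndarray:
        p = self._arrays
        if not np.all(np.isfinite(y)):
            raise EngineIntegrityError(f"non-finite state at t={t} min")
        yc = np.maximum(y, 0.0)
        dy = np.zeros(N_STATE)

        fu = p["fu"]
        avol = np.empty(N_ORG + 2)
        avol[:N_ORG] = yc[:N_ORG] / p["v"]
        avol[ART] = yc[ART] / p["v_art"]
        avol[VEN] = yc[VEN] / p["v_ven"]
        cp = self._plasma_conc(avol, p["kappa"], p["beta"], p["km_eq"], fu)
        cwb_out = self._wb(cp[:N_ORG])
        cwb_art = avol[ART]
        cwb_ven = avol[VEN]
        cp_art = cp[ART]
        cu = fu * cp[:N_ORG]

        # systemic metabolism
        met = p["met_vmax"] * cu / (p["km_met"] + cu)
        dy[TRK0 + 2] += met.sum()
        dy[TRK0 + 5] = met[LIVER]

        # slow binding pools
        b = yc[SLOW0:SLOW0 + len(SLOW_SITES)]
        dbound = p["slow_kon"] * cu[p["slow_org"]] * (p["slow_cap"] - b) - p["slow_koff"] * b
        dy[SLOW0:SLOW0 + len(SLOW_SITES)] = dbound

        # brain P-gp efflux back to venous blood
        br = p["brain_pgp_vmax"] * cu[BRAIN] / (p["pgp_km"] + cu[BRAIN])

        # organ balances
        q = p["q_eff"]
        dorg = q * (cwb_art - cwb_out) - met
        dorg[LUNG] = p["co"] * (cwb_ven - cwb_out[LUNG])
        dorg[BRAIN] -= br
        np.add.at(dorg, p["slow_org"], -dbound)

        # mucosa
        m = yc[MUC0:MUC0 + 6]
        cm = m / p["vm"]
        cum = fu * cm
        d_lum = yc[LUMD0:LUMD0 + 7]
        j_abs = p["perm"] * p["area"] * (d_lum[1:] / p["vf"][1:]) * 1e-3
        j_pgp = p["pgp_vmax"] * cum / (p["pgp_km"] + cum)
        j_met = p["clii"] * cum
        j_out = p["clb"] * cum
        j_in = p["clb"] * fu * cp_art
        dy[MUC0:MUC0 + 6] = j_abs - j_pgp - j_met - j_out + j_in

        # portal vein (algebraic mixing) and liver
        portal = (q[list(PORTAL_IDX)] * cwb_out[list(PORTAL_IDX)]).sum() + j_out.sum()
        q_hep_out = q[LIVER] + p["q_portal"]
        # portal organs keep their arterial inflow / portal outflow from dorg;
        # their return is routed through the liver, not venous blood
        dorg[LIVER] = q[LIVER] * cwb_art + portal - q_hep_out * self._wb(cp[LIVER]) \
            - met[LIVER] - dbound[2]

        dy[:N_ORG] = dorg

        # blood
        dy[ART] = p["co"] * (cwb_out[LUNG] - cwb_art) - j_in.sum()
        sys_return = (q[list(SYSTEMIC_IDX)] * cwb_out[list(SYSTEMIC_IDX)]).sum()
        dy[VEN] = (sys_return + (p["q_shunt"] + p["q_bypass"]) * cwb_art
                   + q_hep_out * self._wb(cp[LIVER])
                   + br + iv_rate_umol_min - p["co"] * cwb_ven)

        # lumen transit, precipitation, absorption, efflux return
        s_lum = yc[LUMS0:LUMS0 + 7]
        kt = p["kt"]
        d_eq = np.minimum(d_lum + s_lum, p["sol_cap"])
        x = p["k_precip"] * (d_lum - d_eq)
        dd = -kt * d_lum - x
        ds = -kt * s_lum + x
        dd[1:] += kt[:-1] * d_lum[:-1]
        ds[1:] += kt[:-1] * s_lum[:-1]
        dd[1:] += j_pgp - j_abs
        dy[LUMD0:LUMD0 + 7] = dd
        dy[LUMS0:LUMS0 + 7] = ds

        # trackers
        dy[TRK0 + 0] = j_abs.sum()
        dy[TRK0 + 1] = j_out.sum()
        dy[TRK0 + 2] += j_met.sum()
        dy[TRK0 + 3] = j_pgp.sum()
        dy[TRK0 + 4] = kt[-1] * (d_lum[-1] + s_lum[-1])
        dy[TRK0 + 6] = j_in.sum()
        return dy

    def jac_sparsity(self) -> np.ndarray:
        """Conservative Jacobian sparsity pattern for the implicit solver."""
        j = np.zeros((N_STATE, N_STATE), dtype=bool)
        rng = np.arange(N_STATE)
        j[rng, rng] = True
        organ_cols = list(range(N_ORG))
        j[organ_cols, ART] = True
        j[LUNG, VEN] = True
        j[LIVER, organ_cols] = True                      # portal mixing
        j[LIVER, MUC0:MUC0 + 6] = True
        j[ART, LUNG] = True
        j[VEN, organ_cols] = True
        j[VEN, ART] = True
        j[VEN, MUC0:MUC0 + 6] = True
        j[VEN, SLOW0:SLOW0 + 4] = True
        for k, (_, i) in enumerate(SLOW_SITES):
            j[SLOW0 + k, i] = True
            j[i, SLOW0 + k] = True
            j[LIVER, SLOW0 + k] = True
        for s in range(6):
            j[MUC0 + s, [ART, LUMD0 + 1 + s]] = True
            j[LUMD0 + 1 + s, MUC0 + s] = True
        for i in range(7):
            j[LUMD0 + i, [LUMD0 + i, LUMS0 + i]] = True
            j[LUMS0 + i, [LUMD0 + i, LUMS0 + i]] = True
            if i > 0:
                j[LUMD0 + i, LUMD0 + i - 1] = True
                j[LUMS0 + i, LUMS0 + i - 1] = True
        j[TRK0:, :] = False
        j[TRK0 + 0, LUMD0:LUMD0 + 7] = True
        j[TRK0 + 1, MUC0:MUC0 + 6] = True
        j[TRK0 + 2, :VEN + 1] = True
        j[TRK0 + 2, MUC0:MUC0 + 6] = True
        j[TRK0 + 3, MUC0:MUC0 + 6] = True
        j[TRK0 + 4, [LUMD0 + 6, LUMS0 + 6]] = True
        j[TRK0 + 5, LIVER] = True
        j[TRK0 + 6, ART] = True
        return j


def assemble_rhs(individual: VirtualIndividual, compound: CompoundModel,
                 doses: list[DoseEvent]):
    """Derivative function ``f(t_min, y) -> dy`` with the IV forcing of ``doses``.

    Oral boluses are instantaneous state jumps handled by :func:`integrate`;
    the returned field covers the continuous dynamics plus IV infusion terms.
    """
    model = CompiledModel(individual, compound)

    def iv_rate(t_min: float) -> float:
        rate = 0.0
        for d in doses:
            if d.route != "iv_infusion":
                continue
            t0 = d.start_h * 60.0
            t1 = t0 + d.infusion_duration_h * 60.0
            if t0 <= t_min < t1:
                rate += d.amount_mg * 1000.0 / compound.phys_chem.molecular_weight_g_mol \
                    / (d.infusion_duration_h * 60.0)
        return rate

    def f(t, y):
        return model.rhs(t, y, iv_rate(t))

    return f


def whole_blood_concentration(state: np.ndarray, individual: VirtualIndividual,
                              compound: CompoundModel) -> float:
    """Venous whole-blood concentration (ng/ml) of a state vector."""
    return float(CompiledModel(individual, compound).whole_blood_ng_ml(np.asarray(state)))


def _dose_amount_umol(d: DoseEvent, mw: float) -> float:
    return d.amount_mg * 1000.0 / mw


def integrate(individual: VirtualIndividual, compound: CompoundModel,
              doses: list[DoseEvent], t_end_h: float, grid_h: float = 0.05,
              solver: SolverOptions = SolverOptions(),
              model: CompiledModel | None = None):
    """Integrate the dosing scenario and return ``(time_h, states)``.

    The time axis is the regular output grid plus every dose boundary; oral
    doses enter as instantaneous additions to the dissolved stomach lumen and
    IV infusions as constant-rate source terms between their boundaries.
    """
    model = model or CompiledModel(individual, compound)
    mw = compound.phys_chem.molecular_weight_g_mol
    t_end = t_end_h * 60.0

    boundaries = {0.0, t_end}
    for d in doses:
        boundaries.add(d.start_h * 60.0)
        if d.route == "iv_infusion":
            boundaries.add((d.start_h + d.infusion_duration_h) * 60.0)
    boundaries = sorted(b for b in boundaries if 0.0 <= b <= t_end)

    grid = np.arange(0.0, t_end + 1e-9, grid_h * 60.0)
    times_all = np.unique(np.concatenate([grid, np.array(boundaries)]))

    sparsity = model.jac_sparsity()
    y = model.initial_state()
    out_t: list[np.ndarray] = []
    out_y: list[np.ndarray] = []

    for t0, t1 in zip(boundaries[:-1], boundaries[1:]):
        for d in doses:
            if d.route == "oral_solution" and abs(d.start_h * 60.0 - t0) < 1e-9:
                y[LUMD0] += _dose_amount_umol(d, mw)
        rate = 0.0
        for d in doses:
            if d.route == "iv_infusion":
                a, b = d.start_h * 60.0, (d.start_h + d.infusion_duration_h) * 60.0
                if a <= t0 + 1e-9 and t1 <= b + 1e-9:
                    rate += _dose_amount_umol(d, mw) / (b - a)
        t_eval = times_all[(times_all >= t0 - 1e-9) & (times_all <= t1 + 1e-9)]
        t_eval[0], t_eval[-1] = t0, t1
        sol = solve_ivp(
            lambda t, yy: model.rhs(t, yy, rate), (t0, t1), y,
            method=solver.method, rtol=solver.rtol, atol=solver.atol,
            t_eval=t_eval, jac_sparsity=sparsity,
        )
        if not sol.success:
            raise EngineIntegrityError(
                f"integration failed in [{t0 / 60:.2f}, {t1 / 60:.2f}] h: {sol.message}")
        y = sol.y[:, -1].copy()
        if np.any(y < -1e-6 * max(1.0, np.abs(y).max())):
            raise EngineIntegrityError("state went negative beyond tolerance")
        keep = slice(None) if not out_t else slice(1, None)
        out_t.append(sol.t[keep])
        out_y.append(sol.y[:, keep])

    time_min = np.concatenate(out_t)
    states = np.concatenate(out_y, axis=1).T
    return time_min / 60.0, states
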