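"""Engine-level process rates, mass balance and solver behaviour."""

import copy

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cyclopbpk import CyclosporinePBPK, build_reference_individual
from cyclopbpk.compound import BindingSite, CompoundModel
from cyclopbpk.engine import (
    TRK0,
    CompiledModel,
    EngineIntegrityError,
    LUMD0,
    LUMS0,
    assemble_rhs,
    binding_rate,
    gi_absorption_rate,
    gut_wall_extraction_rate,
    mm_metabolism_rate,
    pgp_efflux_rate,
    whole_blood_concentration,
)

LIVER_SITE = BindingSite("liver", 0.15, 0.00271, "per_h", 38.7)


class TestBindingRate:
    def test_empty_system_is_stationary(self, compound):
        for site in compound.binding_sites:
            assert binding_rate(0.0, 0.0, site) == 0.0

    def test_steady_state_at_km_is_half_capacity(self):
        """Integrating dB/dt at fixed C_u = K_M converges to B_C/2 (liver: 19.35)."""
        c = LIVER_SITE.k_m_umol_l
        t_end = 12.0 / LIVER_SITE.k_off_per_min  # several relaxation times
        sol = solve_ivp(lambda t, b: [binding_rate(c, b[0], LIVER_SITE)],
                        (0, t_end), [0.0], rtol=1e-10, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(19.35, rel=1e-4)

    @pytest.mark.parametrize("tissue", ["lung", "kidney", "blood_cells"])
    def test_equilibrium_matches_isotherm(self, compound, tissue):
        site = compound.site(tissue)
        for c in (0.01, site.k_m_umol_l, 5.0):
            expected = site.b_c_umol_l * c / (site.k_m_umol_l + c)
            t_end = 20.0 / (site.k_off_per_min * (1 + c / site.k_m_umol_l))
            sol = solve_ivp(lambda t, b: [binding_rate(c, b[0], site)],
                            (0, t_end), [0.0], method="Radau", rtol=1e-10, atol=1e-12)
            assert sol.y[0, -1] == pytest.approx(expected, rel=1e-3)

    def test_saturation_limit(self):
        # at C_u >> K_M the stationary bound amount approaches capacity
        c = 1e4 * LIVER_SITE.k_m_umol_l
        eq = LIVER_SITE.b_c_umol_l * c / (LIVER_SITE.k_m_umol_l + c)
        assert eq == pytest.approx(LIVER_SITE.b_c_umol_l, rel=1e-3)

    def test_overfull_pool_rejected(self):
        with pytest.raises(EngineIntegrityError):
            binding_rate(1.0, 50.0, LIVER_SITE)


class TestMetabolismRates:
    def test_liver_rate_at_km(self, compound, reference_individual):
        # 1800 g liver, relative abundance 1, C_u = K_M: 0.78*1800*0.5 nmol/min
        rate = mm_metabolism_rate(0.5, "liver", compound.metabolism,
                                  reference_individual.organs)
        assert rate * 1000 == pytest.approx(702.0, rel=1e-12)

    def test_first_order_limit(self, compound, reference_individual):
        c = 1e-6
        rate = mm_metabolism_rate(c, "liver", compound.metabolism,
                                  reference_individual.organs)
        linear = 0.78e-3 * 1800 * c / 0.5
        assert rate == pytest.approx(linear, rel=1e-4)

    def test_unknown_organ_rejected(self, compound, reference_individual):
        with pytest.raises(KeyError):
            mm_metabolism_rate(0.1, "spleen", compound.metabolism,
                               reference_individual.organs)

    def test_gut_wall_rates_normalize_to_cl_ii(self, compound):
        c = 0.7
        segs = compound.metabolism.b_c_by_segment_umol_l
        total = sum(gut_wall_extraction_rate(c, s, compound.metabolism) for s in segs)
        assert total == pytest.approx(compound.metabolism.cl_ii_l_min * c, rel=1e-12)

    def test_duodenal_weight_exceeds_upper_ileum(self, compound):
        c = 1.0
        duo = gut_wall_extraction_rate(c, "duodenum", compound.metabolism)
        uil = gut_wall_extraction_rate(c, "upper_ileum", compound.metabolism)
        assert duo > uil

    def test_zero_concentration_zero_rate(self, compound):
        assert gut_wall_extraction_rate(0.0, "duodenum", compound.metabolism) == 0.0


class TestPgpEfflux:
    def test_half_maximal_at_km(self, compound):
        eff = compound.efflux
        full = pgp_efflux_rate(1e6, "colon", eff, 0.06)
        half = pgp_efflux_rate(eff.k_m_umol_l, "colon", eff, 0.06)
        assert half == pytest.approx(full / 2, rel=1e-3)

    def test_aboral_distribution_ratio(self, compound):
        eff, c, v = compound.efflux, 0.05, 0.04
        ileum = pgp_efflux_rate(c, "upper_ileum", eff, v) \
            + pgp_efflux_rate(c, "lower_ileum", eff, v)
        jejunum = pgp_efflux_rate(c, "upper_jejunum", eff, v) \
            + pgp_efflux_rate(c, "lower_jejunum", eff, v)
        assert ileum / jejunum == pytest.approx(0.55 / 0.38, rel=1e-12)

    def test_colon_carries_baseline_capacity(self, compound):
        assert compound.efflux.segment_capacity()["colon"] == pytest.approx(1.0)


def test_gi_absorption_empty_lumen(compound):
    assert gi_absorption_rate(0.0, "duodenum", 4.5e-5, 1e4, 0.05) == 0.0


class TestWholeBlood:
    def test_zero_state(self, reference_individual, compound):
        model = CompiledModel(reference_individual, compound)
        assert model.whole_blood_ng_ml(model.initial_state()) == 0.0

    def test_one_micromolar_is_mw_in_ng_ml(self, reference_individual, compound):
        model = CompiledModel(reference_individual, compound)
        state = model.initial_state()
        v_ven = reference_individual.organs.loc["blood_venous", "volume_l"]
        state[14] = v_ven * 1.0  # 1 µmol/L in venous blood
        assert whole_blood_concentration(state, reference_individual, compound) == \
            pytest.approx(1203.0)

    def test_whole_blood_at_least_plasma_free(self, reference_individual, compound):
        model = CompiledModel(reference_individual, compound)
        fu = compound.plasma_binding.fraction_unbound
        for cp in (1e-4, 0.01, 0.5, 5.0):
            assert model._wb(cp) >= fu * cp


class TestAssembledSystem:
    def test_zero_state_zero_derivative(self, reference_individual, compound):
        f = assemble_rhs(reference_individual, compound, [])
        dy = f(0.0, np.zeros(len(CompiledModel(reference_individual, compound).initial_state())))
        assert np.allclose(dy, 0.0)

    def test_nan_state_raises(self, reference_individual, compound):
        model = CompiledModel(reference_individual, compound)
        y = model.initial_state()
        y[0] = np.nan
        with pytest.raises(EngineIntegrityError):
            model.rhs(0.0, y)

    def test_mass_conserved_without_clearances(self, compound):
        """With metabolism and efflux disabled, dosed material is conserved."""
        cfg = copy.deepcopy(compound.raw)
        cfg["metabolism"]["systemic"]["v_max_nmol_min_g"] = 0.0
        cfg["metabolism"]["intestinal"]["cl_ii_l_h"] = 0.0
        cfg["efflux"]["v_max_nmol_ml_min"] = 0.0
        inert = CompoundModel.from_dict(cfg)
        run = CyclosporinePBPK.reference(inert).simulate_oral(100.0, t_end_h=12.0,
                                                              grid_h=0.25)
        assert run.mass_balance_error() < 1e-3
        assert run.tracker("metabolized_total") == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("fixture", ["oral_100_run", "iv_reference_run", "oral_600_run"])
    def test_mass_balance_within_tenth_percent(self, fixture, request):
        run = request.getfixturevalue(fixture)
        assert run.mass_balance_error() < 1e-3

    def test_trackers_monotone(self, oral_100_run):
        trk = oral_100_run.states[:, TRK0:]
        assert (np.diff(trk, axis=0) >= -1e-9).all()

    def test_body_amount_dissipates_after_single_dose(self, oral_100_run):
        conc = oral_100_run.profile.conc_ng_ml
        assert conc[-1] < 0.5 * conc.max()

    def test_dose_linearity_in_first_order_regime(self, reference_model):
        """A 1000-fold dose reduction scales the whole trajectory 1000-fold."""
        lo = reference_model.simulate_oral(1e-4, t_end_h=12.0, grid_h=0.25)
        hi = reference_model.simulate_oral(0.1, t_end_h=12.0, grid_h=0.25)
        c_lo, c_hi = lo.profile.conc_ng_ml, hi.profile.conc_ng_ml
        mask = c_hi > 1e-2 * c_hi.max()
        ratio = c_hi[mask] / np.maximum(c_lo[mask], 1e-300)
        assert np.allclose(ratio, 1000.0, rtol=0.01)

    def test_solver_tolerance_halving_stable(self, reference_model, oral_100_run):
        from cyclopbpk.engine import SolverOptions
        from cyclopbpk.simulation import DosingRegimen, simulate
        tight = simulate(reference_model.individual, reference_model.compound,
                         oral_100_run.regimen,
                         solver=SolverOptions(rtol=0.5e-8, atol=0.5e-10))
        m0, m1 = oral_100_run.metrics(), tight.metrics()
        assert abs(m1.auc_t_end_ng_h_ml / m0.auc_t_end_ng_h_ml - 1) < 0.005
        assert abs(m1.c_max_ng_ml / m0.c_max_ng_ml - 1) < 0.005

    def test_high_dose_precipitates_low_dose_absorbs(self, oral_100_run, oral_600_run):
        """The 190 µg/ml solubility ceiling caps absorption at 600 mg."""
        solid_600 = oral_600_run.states[:, LUMS0:LUMS0 + 7].sum(axis=1)
        assert solid_600.max() > 0.0
        fa_100 = oral_100_run.metrics().f_a
        fa_600 = oral_600_run.metrics().f_a
        assert fa_600 < 0.9 * fa_100
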