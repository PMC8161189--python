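"""Model-object facade over the PBPK machinery.

``CyclosporinePBPK`` pairs a virtual individual with the cyclosporine
compound parameterization; its methods run dosing scenarios and return
:class:`~cyclopbpk.simulation.SimulationResult` objects carrying the profile,
metrics and bookkeeping trackers.
"""

from __future__ import annotations

from dataclasses import dataclass

from .compound import CompoundModel, load_cyclosporine
from .engine import DoseEvent, SolverOptions
from .physiology import Demographics, VirtualIndividual, build_individual, \
    build_reference_individual
from .simulation import DEFAULT_SOLVER, DosingRegimen, SimulationResult, simulate, \
    trough_regimen

__all__ = ["CyclosporinePBPK"]


@dataclass
class CyclosporinePBPK:
    individual: VirtualIndividual
    compound: CompoundModel
    solver: SolverOptions = DEFAULT_SOLVER

    @classmethod
    def reference(cls, compound: CompoundModel | None = None) -> "CyclosporinePBPK":
        """Model for the average European male calibration subject (30 y, 73 kg, 176 cm)."""
        return cls(build_reference_individual(), compound or load_cyclosporine())

    @classmethod
    def for_patient(cls, demographics: Demographics,
                    compound: CompoundModel | None = None) -> "CyclosporinePBPK":
        return cls(build_individual(demographics), compound or load_cyclosporine())

    def simulate(self, regimen: DosingRegimen) -> SimulationResult:
        return simulate(self.individual, self.compound, regimen, solver=self.solver)

    def simulate_oral(self, dose_mg: float, t_end_h: float = 24.0,
                      grid_h: float = 0.05) -> SimulationResult:
        ev = DoseEvent(route="oral_solution", amount_mg=dose_mg, start_h=0.0)
        return self.simulate(DosingRegimen(events=(ev,), t_end_h=t_end_h, output_grid_h=grid_h))

    def simulate_iv(self, dose_mg: float, infusion_h: float, t_end_h: float = 24.0,
                    grid_h: float = 0.05) -> SimulationResult:
        ev = DoseEvent(route="iv_infusion", amount_mg=dose_mg, start_h=0.0,
                       infusion_duration_h=infusion_h)
        return self.simulate(DosingRegimen(events=(ev,), t_end_h=t_end_h, output_grid_h=grid_h))

    def predict_trough(self, dose_mg: float, interval_h: float = 12.0,
                       n_doses: int = 8) -> float:
        """Steady-state whole-blood trough (ng/ml) for q12h oral dosing over 4 days."""
        if dose_mg == 0:
            return 0.0
        result = self.simulate(trough_regimen(dose_mg, interval_h=interval_h, n_doses=n_doses))
        return result.profile.at(interval_h * n_doses)
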