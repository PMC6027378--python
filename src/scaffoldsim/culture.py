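"""Top-level culture experiment runner.

Builds the voxelized unit for a design, runs the transient coupled
simulation (flow / glucose / lactate / pH / biomass) under one set of
operating conditions, and reports the culture-efficiency indicator

    CE = (mean final cell density - mean initial density) / initial,

with the mean taken over the monolayer shell, the habitat of the seeded
cells.  CE = 0 means no net growth, CE = -1 total loss of the population.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import transport
from .geometry import (GeometryMetrics, OccludedDomainError, UnitDesign,
                       design_metrics, voxelize)
from .kinetics import KineticParams

__all__ = ["OperatingConditions", "CultureResult", "run_culture", "sweep"]

#: Inlet glucose concentrations studied in the velocity sweeps [kg/m^3]
#: (0.059, 1.54, 3.02 and 4.5 x 1e-3 g/cm^3).
GLIN_SWEEP = (0.059, 1.54, 3.02, 4.5)
#: Seeding densities studied [cells/cm^3].
DENSITY_SWEEP = (2e7, 5e7, 10e7)


@dataclass(frozen=True)
class OperatingConditions:
    """Bioreactor operating point (SI units unless noted).

    Defaults reproduce the headline operating point: 3 mm/s plug inflow,
    4.5 kg/m^3 (= 4.5e-3 g/cm^3) inlet glucose, 5e7 cells/cm^3 seeded, one
    hour time step.
    """

    inlet_velocity: float = 3e-3          # m/s
    glin: float = 4.5                     # kg/m^3
    initial_cell_density: float = 5e7     # cells/cm^3
    duration: float = 120 * 3600.0        # s
    dt: float = 3600.0                    # s

    def __post_init__(self):
        if self.inlet_velocity <= 0 or self.glin < 0 or \
                self.initial_cell_density <= 0 or self.dt <= 0:
            raise ValueError("operating conditions must be positive")
        if self.duration < 0:
            raise ValueError("duration must be nonnegative")
        if self.duration > 0 and self.dt > self.duration:
            raise ValueError("dt must not exceed duration")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def replace(self, **kw) -> "OperatingConditions":
        return replace(self, **kw)


@dataclass
class CultureResult:
    """Outcome of one culture run."""

    ce: float
    initial_mean_density_cm3: float
    final_mean_density_cm3: float
    metrics: GeometryMetrics
    tau_mean_Pa: float
    tau_max_Pa: float
    occluded: bool
    trajectory: pd.DataFrame
    design: UnitDesign
    conditions: OperatingConditions


def run_culture(design: UnitDesign, oc: OperatingConditions,
                p: KineticParams | None = None, resolution: int = 32,
                gate_mode: str = "remove", flow_update_interval: int = 1,
                occlusion: str = "static",
                max_area_density: float | None = None) -> CultureResult:
    """Simulate one culture and compute its efficiency.

    ``occlusion`` controls blocked units (e.g. tangent inscribed fibers,
    delta = r on both face pairs, which close the pore at its throat):
    ``"static"`` falls back to a quiescent diffusion-fed culture, which
    keeps such designs comparable within a campaign; ``"error"`` raises
    :class:`OccludedDomainError` instead.

    The run is deterministic: identical inputs give bit-identical results.
    """
    p = p or KineticParams()
    if occlusion not in ("static", "error"):
        raise ValueError("occlusion must be 'static' or 'error'")
    domain = voxelize(design, resolution, dc_um=p.dc * 1e6)
    if domain.occluded and occlusion == "error":
        raise OccludedDomainError(
            "occluded domain: unit blocked at its throat")
    state = transport.init_state(domain, p, oc.initial_cell_density, oc.glin)
    rho0 = state.mean_shell_density_cm3(p)
    if oc.n_steps == 0:
        traj = pd.DataFrame()
        final = state
        tau_mean = tau_max = 0.0
    else:
        final, traj = transport.integrate(
            state, domain, p, oc.dt, oc.n_steps, oc.inlet_velocity,
            oc.glin, gate_mode=gate_mode,
            flow_update_interval=flow_update_interval,
            max_area_density=max_area_density)
        tau_mean = float(traj["tau_mean_Pa"].iloc[-1])
        tau_max = float(traj["tau_max_Pa"].iloc[-1])
    rho1 = final.mean_shell_density_cm3(p)
    ce = (rho1 - rho0) / rho0 if rho0 > 0 else 0.0
    return CultureResult(
        ce=ce, initial_mean_density_cm3=rho0, final_mean_density_cm3=rho1,
        metrics=design_metrics(design, domain), tau_mean_Pa=tau_mean,
        tau_max_Pa=tau_max, occluded=domain.occluded, trajectory=traj,
        design=design, conditions=oc)


def sweep(oc_grid, design: UnitDesign, p: KineticParams | None = None,
          **run_kwargs):
    """Evaluate one design over a grid of operating conditions.

    Returns ``(table, results)``: a DataFrame sorted by (inlet velocity,
    inlet glucose) with one row per condition, and the raw results (None
    where a run failed; failures are recorded in the ``error`` column and
    do not abort the sweep).
    """
    oc_grid = list(oc_grid)
    if not oc_grid:
        raise ValueError("operating-condition grid is empty")
    rows, results = [], []
    for oc in oc_grid:
        row = {"inlet_velocity": oc.inlet_velocity, "glin": oc.glin,
               "initial_cell_density": oc.initial_cell_density,
               "duration_h": oc.duration / 3600.0}
        try:
            res = run_culture(design, oc, p, **run_kwargs)
            row.update(ce=res.ce,
                       final_mean_density_cm3=res.final_mean_density_cm3,
                       tau_mean_Pa=res.tau_mean_Pa, error="")
        except Exception as exc:  # noqa: BLE001 - recorded per row
            res = None
            row.update(ce=np.nan, final_mean_density_cm3=np.nan,
                       tau_mean_Pa=np.nan, error=str(exc))
        rows.append(row)
        results.append(res)
    order = np.lexsort(([r["glin"] for r in rows],
                        [r["inlet_velocity"] for r in rows]))
    table = pd.DataFrame([rows[i] for i in order]).reset_index(drop=True)
    results = [results[i] for i in order]
    return table, results
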