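"""Coupled scalar transport and biomass dynamics on the voxel grid.

Three balances evolve during a culture run:

* glucose — a single fluid-phase field ``c_gf`` with the cell-phase
  concentration slaved through the linear interfacial partition
  ``c_gc = Keq * c_gf`` inside biomass voxels.  The transient capacity of a
  biomass voxel is therefore ``eps_f + Keq * eps_c`` and its effective
  diffusivity ``Dgf + Keq * Dgc``; the Michaelis-Menten uptake acts as a
  sink.  The field is advected by the (penalized) local flow velocity.
* lactate — fluid-phase scalar with source equal to twice the glucose
  actually consumed in the same step, which makes the cumulative
  lactate/glucose budget stoichiometric by construction.
* biomass — the cell volume fraction ``eps_c`` confined to the monolayer
  shell, grown with an exact exponential update per step (the growth rate
  is frozen within a step), gated by pH viability and capped per
  attachment-surface column.

Spatial discretization: cell-centered finite volumes, harmonic-mean face
diffusivities, first-order upwind advection on the staggered face fluxes
(divergence-free by construction).  Time discretization: implicit Euler
with the uptake sink linearized about the previous concentration (kept
implicit in the new value, which preserves positivity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import kinetics
from .geometry import SOLID, VoxelDomain
from .kinetics import KineticParams

__all__ = [
    "CultureState",
    "TransportError",
    "ScalarTransport",
    "init_state",
    "step_glucose",
    "step_lactate",
    "step_biomass",
    "integrate",
    "cell_volume_m3",
]


class TransportError(RuntimeError):
    pass


def cell_volume_m3(p: KineticParams) -> float:
    """Volume of one chondrocyte, modeled as a sphere of diameter dc."""
    return math.pi / 6.0 * p.dc ** 3


@dataclass
class CultureState:
    """Evolving culture fields on the voxel grid (SI units).

    ``c_gf`` fluid-phase glucose [kg/m^3]; ``c_l`` lactate [kg/m^3];
    ``eps_c`` cell volume fraction (nonzero only in the monolayer shell);
    ``shell`` the fixed biomass habitat mask; ``face_shells`` the per-face
    partition of the shell used for the attachment-area cap.  Budgets track
    cumulative glucose consumed and lactate produced [kg].
    """

    c_gf: np.ndarray
    c_l: np.ndarray
    eps_c: np.ndarray
    shell: np.ndarray
    face_shells: dict
    t: float = 0.0
    glucose_consumed: float = 0.0
    lactate_produced: float = 0.0
    clipped_mass: float = 0.0
    last_uptake: np.ndarray | None = None  # kg/m^3/s, from last glucose step

    def copy(self) -> "CultureState":
        return CultureState(
            c_gf=self.c_gf.copy(), c_l=self.c_l.copy(),
            eps_c=self.eps_c.copy(), shell=self.shell,
            face_shells=self.face_shells, t=self.t,
            glucose_consumed=self.glucose_consumed,
            lactate_produced=self.lactate_produced,
            clipped_mass=self.clipped_mass,
            last_uptake=None if self.last_uptake is None
            else self.last_uptake.copy())

    def c_gc(self, p: KineticParams) -> np.ndarray:
        """Cell-phase glucose via the interfacial partition (shell only)."""
        return p.Keq * self.c_gf * np.where(self.shell, 1.0, 0.0)

    def ph(self) -> np.ndarray:
        return kinetics.ph_from_lactate(self.c_l)

    def cell_density(self, p: KineticParams) -> np.ndarray:
        """Cell number density [cells/m^3] per voxel."""
        return self.eps_c / cell_volume_m3(p)

    def mean_shell_density_cm3(self, p: KineticParams) -> float:
        """Mean cell density over the monolayer shell [cells/cm^3]."""
        if not self.shell.any():
            return 0.0
        return float(self.eps_c[self.shell].mean() / cell_volume_m3(p) / 1e6)


def init_state(domain: VoxelDomain, p: KineticParams,
               initial_density_cm3: float, glin: float) -> CultureState:
    """Fresh-medium initial state with a uniform monolayer on the shell.

    ``initial_density_cm3`` is the seeded cell density [cells/cm^3] inside
    the biomass shell; ``glin`` the inlet (and initial) fluid glucose
    concentration [kg/m^3].
    """
    shell = domain.biomass
    eps0 = initial_density_cm3 * 1e6 * cell_volume_m3(p)
    if eps0 > 1:
        raise ValueError("initial cell density exceeds close packing")
    eps = np.where(shell, eps0, 0.0)
    flowm = domain.labels != SOLID
    c_gf = np.where(flowm, glin, 0.0)
    c_l = np.zeros(domain.shape)
    face_shells = _face_shells(domain)
    return CultureState(c_gf=c_gf, c_l=c_l, eps_c=eps, shell=shell,
                        face_shells=face_shells)


def _face_shells(domain: VoxelDomain) -> dict:
    """Partition of the shell per cultured face (for the column cap)."""
    design = domain.design
    out = {}
    if design is None:
        if domain.biomass.any():
            out["bottom"] = domain.biomass
        return out
    # attribute each biomass voxel to the cultured cap(s) it overlays
    from .geometry import _shell_mask
    r = design.r
    h = domain.spacing_um
    c = [(np.arange(domain.shape[i]) + 0.5) * h[i] for i in range(3)]
    X = c[0][:, None, None]
    Y = c[1][None, :, None]
    Z = c[2][None, None, :]
    for face in design.cultured_surfaces:
        d = design.delta_of(face)
        if face in ("bottom", "top"):
            side = -1 if face == "bottom" else +1
            mask = _shell_mask(X, Z, r, d, side, 1e9)
        else:
            side = -1 if face == "back" else +1
            mask = _shell_mask(Z, Y, r, d, side, 1e9)
        out[face] = mask & domain.biomass
    return out


FACE_NORMAL_AXIS = {"top": 2, "bottom": 2, "front": 1, "back": 1}


class ScalarTransport:
    """Implicit advection-diffusion-reaction stepper for one voxel domain.

    Builds and solves the sparse linear system for a cell-centered scalar:
    implicit Euler transient term, harmonic-mean face diffusion, upwind
    advection on staggered face fluxes, linearized volumetric sink and
    explicit source.  Boundary conditions: Dirichlet value at the open
    inlet plane (advective + diffusive), upwind outflow at the outlet,
    no-flux at solid and lateral walls.  ``closed=True`` seals inlet and
    outlet (batch/closed-box mode, used by conservation checks).

    The ILU preconditioner is refreshed lazily; between refreshes the
    previous factorization serves as preconditioner for BiCGStab.
    """

    def __init__(self, domain: VoxelDomain, closed: bool = False,
                 ilu_refresh: int = 8):
        self.domain = domain
        self.F = domain.labels != SOLID
        self.idx = -np.ones(domain.shape, dtype=np.int64)
        self.N = int(self.F.sum())
        self.idx[self.F] = np.arange(self.N)
        self.closed = closed
        self.ilu_refresh = ilu_refresh
        self._ilu = {}
        self._ilu_age = {}
        self.h = domain.spacing_m
        self.V = domain.voxel_volume_m3()

    # -------------------------------------------------------------- #
    def _diffusion(self, D_cell):
        """Sparse diffusion operator (positive semi-definite part)."""
        F, idx, h = self.F, self.idx, self.h
        n = F.shape
        rows, cols, vals = [], [], []
        diag = np.zeros(self.N)
        A_face = [self.V / hh for hh in h]
        for ax in range(3):
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[ax] = slice(0, n[ax] - 1)
            sl_hi[ax] = slice(1, n[ax])
            both = F[tuple(sl_lo)] & F[tuple(sl_hi)]
            DL = D_cell[tuple(sl_lo)][both]
            DR = D_cell[tuple(sl_hi)][both]
            Df = 2.0 * DL * DR / (DL + DR)
            a = Df * A_face[ax] / h[ax]
            iL = idx[tuple(sl_lo)][both]
            iR = idx[tuple(sl_hi)][both]
            rows += [iL, iR]
            cols += [iR, iL]
            vals += [-a, -a]
            np.add.at(diag, iL, a)
            np.add.at(diag, iR, a)
        rows.append(np.arange(self.N))
        cols.append(np.arange(self.N))
        vals.append(diag)
        return sp.csr_matrix((np.concatenate(vals),
                              (np.concatenate(rows), np.concatenate(cols))),
                             shape=(self.N, self.N))

    def _advection(self, flow):
        """Upwind advection operator from staggered face fluxes."""
        F, idx, h = self.F, self.idx, self.h
        n = F.shape
        A_face = [self.V / hh for hh in h]
        rows, cols, vals = [], [], []
        diag = np.zeros(self.N)
        comps = (flow.u, flow.v, flow.w)
        for ax in range(3):
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[ax] = slice(0, n[ax] - 1)
            sl_hi[ax] = slice(1, n[ax])
            both = F[tuple(sl_lo)] & F[tuple(sl_hi)]
            faces = [slice(None)] * 3
            faces[ax] = slice(1, n[ax])  # interior faces
            q = comps[ax][tuple(faces)][both] * A_face[ax]
            iL = idx[tuple(sl_lo)][both]
            iR = idx[tuple(sl_hi)][both]
            qp = np.maximum(q, 0.0)   # L -> R
            qm = np.minimum(q, 0.0)   # R -> L
            np.add.at(diag, iL, qp)
            np.add.at(diag, iR, -qm)
            rows += [iR, iL]
            cols += [iL, iR]
            vals += [-qp, qm]
        rows.append(np.arange(self.N))
        cols.append(np.arange(self.N))
        vals.append(diag)
        return sp.csr_matrix((np.concatenate(vals),
                              (np.concatenate(rows), np.concatenate(cols))),
                             shape=(self.N, self.N))

    # -------------------------------------------------------------- #
    def step(self, c, theta, D_cell, flow, dt, inlet_value=0.0,
             sink_lin=None, source=None, key="scalar",
             outlet_value=None):
        """Advance one implicit Euler step; returns (c_new, applied_sink).

        ``sink_lin`` is the linearized sink coefficient k [1/s] such that
        the applied sink is k * c_new [kg/m^3/s]; ``source`` an explicit
        volumetric source [kg/m^3/s].  ``outlet_value`` switches the
        outlet from free outflow to a Dirichlet value (two-sided fixed
        concentrations, used by diffusion benchmarks).
        """
        F, idx = self.F, self.idx
        n = F.shape
        V, h = self.V, self.h
        M = self._diffusion(D_cell)
        b = np.zeros(self.N)
        trans = theta[F] * V / dt
        M = M + sp.diags(trans)
        b += trans * c[F]
        if flow is not None and not self.closed:
            M = M + self._advection(flow)
        if not self.closed:
            # inlet plane: Dirichlet value by advective + diffusive flux
            inlet = F[0]
            ii = idx[0][inlet]
            A0 = V / h[0]
            if flow is not None:
                q_in = flow.u[0][inlet] * (h[1] * h[2])
            else:
                q_in = 0.0
            dcoef = 2.0 * D_cell[0][inlet] * A0 / h[0]
            M = M + sp.csr_matrix(
                (dcoef, (ii, ii)), shape=(self.N, self.N))
            b_in = np.zeros(self.N)
            b_in[ii] = q_in * inlet_value + dcoef * inlet_value
            b += b_in
            # outlet: upwind advective outflow, diffusive zero-gradient
            # (or a Dirichlet value when requested)
            outlet = F[-1]
            io = idx[-1][outlet]
            if flow is not None:
                q_out = np.maximum(flow.u[-1][outlet], 0.0) * (h[1] * h[2])
                M = M + sp.csr_matrix(
                    (q_out, (io, io)), shape=(self.N, self.N))
            if outlet_value is not None:
                dco = 2.0 * D_cell[-1][outlet] * A0 / h[0]
                M = M + sp.csr_matrix(
                    (dco, (io, io)), shape=(self.N, self.N))
                b_out = np.zeros(self.N)
                b_out[io] = dco * outlet_value
                b += b_out
        if sink_lin is not None:
            M = M + sp.diags(sink_lin[F] * V)
        if source is not None:
            b += source[F] * V

        c_new = self._solve(M.tocsr(), b, x0=c[F], key=key)
        applied = np.zeros(n)
        if sink_lin is not None:
            tmp = np.zeros(n)
            tmp[F] = c_new
            applied = sink_lin * tmp
        out = np.zeros(n)
        out[F] = c_new
        return out, applied

    def _solve(self, M, b, x0, key):
        age = self._ilu_age.get(key, self.ilu_refresh)
        if key not in self._ilu or age >= self.ilu_refresh:
            self._ilu[key] = spla.spilu(M.tocsc(), drop_tol=1e-5,
                                        fill_factor=15.0)
            self._ilu_age[key] = 0
        self._ilu_age[key] += 1
        Mop = spla.LinearOperator(M.shape, self._ilu[key].solve)
        x, info = spla.bicgstab(M, b, x0=x0, rtol=1e-11, atol=0.0, M=Mop,
                                maxiter=1000)
        if info != 0:
            # refresh preconditioner and retry; nearly-closed compartments
            # (occluded units) make the system almost singular, so the
            # last resort is a direct sparse solve
            self._ilu[key] = spla.spilu(M.tocsc(), drop_tol=1e-6,
                                        fill_factor=25.0)
            self._ilu_age[key] = 0
            Mop = spla.LinearOperator(M.shape, self._ilu[key].solve)
            x, info = spla.gmres(M, b, x0=x, rtol=1e-11, atol=0.0, M=Mop,
                                 maxiter=5, restart=300)
            if info != 0:
                try:
                    x = spla.spsolve(M.tocsc(), b)
                except Exception as exc:  # pragma: no cover
                    raise TransportError(
                        f"scalar solve '{key}' failed (info={info}): "
                        f"{exc}") from exc
                res = np.linalg.norm(b - M @ x) / max(
                    np.linalg.norm(b), 1e-300)
                if not np.isfinite(res) or res > 1e-8:
                    raise TransportError(
                        f"scalar solve '{key}' failed: direct-solve "
                        f"residual {res:.2e}")
        return x


# ------------------------------------------------------------------ #
def step_glucose(state: CultureState, flow, p: KineticParams, dt: float,
                 transport: ScalarTransport, glin: float) -> CultureState:
    """Implicit update of the phase-weighted glucose content.

    Diffusion acts in both phases (effective diffusivity
    ``Dgf + Keq * Dgc`` in biomass voxels), advection on the fluid phase
    with the local penalized velocity, and the Michaelis-Menten sink
    linearized about the previous concentration.  Inlet glucose is held at
    ``glin``; the outlet is a free outflow.
    """
    theta = np.where(state.shell,
                     (1.0 - state.eps_c) + p.Keq * state.eps_c, 1.0)
    D_cell = np.where(state.shell, p.Dgf + p.Keq * p.Dgc, p.Dgf)
    c_old = state.c_gf
    x_old = state.eps_c * p.Keq * c_old
    Rg_old = p.Vm * x_old / (p.Km + x_old)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(c_old > 1e-30, Rg_old / np.maximum(c_old, 1e-30),
                     p.Vm * state.eps_c * p.Keq / p.Km)
    k = np.where(state.shell, k, 0.0)

    c_new, applied = transport.step(
        c_old, theta, D_cell, flow, dt, inlet_value=glin, sink_lin=k,
        key="glucose")
    neg = c_new < 0
    clipped = -float((c_new[neg] * theta[neg]).sum()) * transport.V
    c_new[neg] = 0.0

    new = state.copy()
    new.c_gf = c_new
    new.last_uptake = applied  # kg/m^3/s actually removed
    consumed = float(applied.sum()) * transport.V * dt
    new.glucose_consumed += consumed
    new.clipped_mass += clipped
    if new.glucose_consumed > 0 and \
            new.clipped_mass > 1e-3 * max(new.glucose_consumed, 1e-30):
        raise TransportError(
            "clipped negative glucose mass exceeds 0.1% of throughput")
    return new


def step_lactate(state: CultureState, flow, p: KineticParams, dt: float,
                 transport: ScalarTransport) -> CultureState:
    """Lactate balance: source = 2x the glucose sink applied this step."""
    if state.last_uptake is None:
        raise TransportError("run step_glucose before step_lactate")
    theta = np.ones(state.c_l.shape)
    D_cell = np.full(state.c_l.shape, p.Dlf)
    source = 2.0 * state.last_uptake
    c_new, _ = transport.step(state.c_l, theta, D_cell, flow, dt,
                              inlet_value=0.0, source=source, key="lactate")
    c_new[c_new < 0] = 0.0
    new = state.copy()
    new.last_uptake = state.last_uptake
    new.c_l = c_new
    new.lactate_produced += 2.0 * float(state.last_uptake.sum()) * \
        transport.V * dt
    return new


def step_biomass(state: CultureState, tau: np.ndarray, p: KineticParams,
                 dt: float, domain: VoxelDomain,
                 gate_mode: str = "remove",
                 max_area_density: float | None = None) -> CultureState:
    """Grow, gate and cap the cell volume fraction.

    Growth uses the exact exponential update ``eps * exp((rg - rd) dt)``
    with the rate frozen within the step.  The pH viability gate then
    zeroes (``gate_mode="remove"``, the literal step-function update) or
    freezes (``"freeze"``) the population in voxels below the threshold.
    Finally the monolayer constraint is enforced: ``eps_c <= 1`` per voxel
    and, per attachment column of each cultured face, at most
    ``max_area_density`` cells per m^2 of attachment surface (default: one
    cell footprint dc^2 per cell).
    """
    if gate_mode not in ("remove", "freeze"):
        raise ValueError("gate_mode must be 'remove' or 'freeze'")
    shell = state.shell
    c_gc = p.Keq * state.c_gf
    # midpoint evaluation of the crowding-dependent rate: second order in
    # dt, exact for a constant rate
    rg0 = kinetics.growth_rate(c_gc, state.eps_c, tau, p)
    eps_half = np.clip(state.eps_c * np.exp((rg0 - p.rd) * dt / 2), 0, 1)
    rg = kinetics.growth_rate(c_gc, eps_half, tau, p)
    eps_new = state.eps_c * np.exp((rg - p.rd) * dt)
    alive = kinetics.viability_step(state.ph(), p.ph_threshold)
    if gate_mode == "remove":
        eps_new = np.where(alive > 0, eps_new, 0.0)
    else:
        eps_new = np.where(alive > 0, eps_new, state.eps_c)
    eps_new = np.where(shell, np.minimum(eps_new, 1.0), 0.0)

    # attachment-area cap, per column normal to each cultured face
    if max_area_density is None:
        max_area_density = 1.0 / p.dc ** 2
    vvol = domain.voxel_volume_m3()
    vcell = cell_volume_m3(p)
    h = domain.spacing_m
    for face, mask in state.face_shells.items():
        ax = FACE_NORMAL_AXIS[face]
        col_area = vvol / h[ax]
        masked = np.where(mask, eps_new, 0.0)
        n_col = masked.sum(axis=ax, keepdims=True) * vvol / vcell
        cap = max_area_density * col_area
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(n_col > cap, cap / np.maximum(n_col, 1e-300),
                             1.0)
        eps_new = np.where(mask, eps_new * scale, eps_new)

    new = state.copy()
    new.last_uptake = state.last_uptake
    new.eps_c = eps_new
    new.t = state.t + dt
    return new


# ------------------------------------------------------------------ #
def integrate(state: CultureState, domain: VoxelDomain, p: KineticParams,
              dt: float, n_steps: int, inlet_velocity: float,
              glin: float, gate_mode: str = "remove",
              flow_update_interval: int = 1,
              max_area_density: float | None = None,
              record_fields: bool = False):
    """Run the coupled quasi-steady culture loop.

    Per step: refresh viscosity from ``eps_c`` and re-solve the steady flow
    (every ``flow_update_interval`` steps), extract the shear field, then
    advance glucose, lactate, the pH gate and the biomass balance.  An
    occluded domain runs in static (diffusion-only) mode with zero flow.

    Returns ``(final_state, diagnostics)`` with one diagnostics row per
    step (pandas DataFrame).
    """
    from .flow import (StokesSolver, shear_magnitude, zero_flow,
                       viscosity_from_cell_fraction)
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    static = domain.occluded
    solver = None if static else StokesSolver(domain)
    transport = ScalarTransport(domain)
    flow = zero_flow(domain) if static else None
    tau = np.zeros(domain.shape)
    rows = []
    snapshots = [] if record_fields else None
    mu = None
    for step in range(n_steps):
        if not static and (step % max(flow_update_interval, 1) == 0
                           or flow is None):
            mu = viscosity_from_cell_fraction(
                np.where(state.shell, state.eps_c, 0.0))
            flow = solver.solve(mu, inlet_velocity, initial_guess=flow)
            tau = shear_magnitude(flow, mu, domain)
            transport._ilu_age = {}  # force preconditioner refresh
        state = step_glucose(state, flow, p, dt, transport, glin)
        state = step_lactate(state, flow, p, dt, transport)
        state = step_biomass(state, tau, p, dt, domain,
                             gate_mode=gate_mode,
                             max_area_density=max_area_density)
        shell = state.shell
        rows.append({
            "t_h": state.t / 3600.0,
            "mean_density_cm3": state.mean_shell_density_cm3(p),
            "glucose_consumed_kg": state.glucose_consumed,
            "lactate_produced_kg": state.lactate_produced,
            "tau_mean_Pa": float(tau[shell].mean()) if shell.any() else 0.0,
            "tau_max_Pa": float(tau[shell].max()) if shell.any() else 0.0,
            "c_gf_min": float(state.c_gf[transport.F].min()),
            "c_l_max": float(state.c_l[transport.F].max()),
            "ph_min": float(state.ph()[transport.F].min()),
            "mass_imbalance": 0.0 if static else flow.mass_imbalance,
        })
        if record_fields:
            snapshots.append(state.copy())
    diag = pd.DataFrame(rows)
    if record_fields:
        return state, diag, snapshots
    return state, diag
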