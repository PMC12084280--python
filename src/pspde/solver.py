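"""Finite-volume method-of-lines solver for phenotype-structured PDEs.

Discretises

    dn/dt = d/dx[ D dn/dx - A n ] + Dbar d2n/dy2 - Abar dn/dy + s n R

on a uniform cell-centred grid: central differences for diffusive fluxes,
first-order upwinding for advection (in both x and y), a midpoint Riemann
sum for the non-local density, and zero-flux boundaries enforced by zeroing
the boundary interface fluxes in x and by ghost reflection in y.  The
problem-dependent interface velocity A is

    diffusion kind:  A = 0
    pressure kind:   A = -mu(y) dP/dx,  P = Pi(rho)
    taxis kind:      A =  chi(y) dS/dx  (plus constant diffusion D)

Time stepping is explicit Euler (refusing time steps above the stability
bound), backward Euler with Picard-lagged non-local terms, or an IMEX step
that treats the negative part of the reaction implicitly (pointwise) and
transport explicitly.  Mass is conserved exactly by construction when R=0;
negativity beyond round-off raises rather than being clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.linalg import LinearOperator, lgmres

from .grids import (
    ConfigurationError,
    GridSpec,
    MacroscopicState,
    PhenotypeDensityField,
    density,
    macroscopic_state,
)
from .models import ModelSpec, SignalSpec, fitness_eval, pressure_eval, signal_rhs
from .profiles import as_profile

__all__ = [
    "FluxField",
    "IntegratorSpec",
    "IntegrationError",
    "advection_at_interfaces",
    "assemble_spatial_flux",
    "phenotype_term",
    "rhs",
    "cfl_bound",
    "step",
    "simulate",
    "SimulationResult",
    "initial_signal",
]


class IntegrationError(RuntimeError):
    """Time step failed (non-convergence or loss of positivity)."""


@dataclass
class FluxField:
    """Interface fluxes: F_x has shape (nx+1, ny), F_y has shape (nx, ny+1)."""

    F_x: np.ndarray
    F_y: np.ndarray | None = None


@dataclass(frozen=True)
class IntegratorSpec:
    scheme: str = "explicit_euler"  # explicit_euler | implicit_euler | imex
    dt: float = 1e-3
    cfl_safety: float = 0.9
    picard_tol: float = 1e-10
    picard_maxiter: int = 50
    linear_tol: float = 1e-12

    def __post_init__(self):
        if self.scheme not in ("explicit_euler", "implicit_euler", "imex"):
            raise ConfigurationError(f"unknown scheme {self.scheme!r}")
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if not (0 < self.cfl_safety <= 1):
            raise ConfigurationError("cfl_safety must lie in (0, 1]")


# ---------------------------------------------------------------------------
# spatial operator


def _pressure_profile(model: ModelSpec, rho: np.ndarray) -> np.ndarray | None:
    if model.pressure is None:
        return None
    return np.asarray(pressure_eval(model.pressure, rho), float)


def advection_at_interfaces(
    model: ModelSpec, macro: MacroscopicState, grid: GridSpec
) -> np.ndarray:
    """Interface advection velocities A, shape (nx+1, ny); boundaries zero."""
    nx, ny = grid.nx, grid.ny
    A = np.zeros((nx + 1, ny))
    if model.motility.kind == "diffusion":
        return A
    coef = model.motility.coefficient(grid.y_centers)  # mu(y) or chi(y)
    if model.motility.kind == "pressure":
        if macro.P is None:
            raise ConfigurationError("pressure-kind advection needs the pressure profile P")
        grad = np.diff(macro.P) / grid.dx  # at interior interfaces
        A[1:nx, :] = -grad[:, None] * coef[None, :]
    else:  # taxis
        if macro.S is None:
            raise ConfigurationError("taxis-kind advection needs the signal profile S")
        grad = np.diff(macro.S) / grid.dx
        A[1:nx, :] = grad[:, None] * coef[None, :]
    return A


def _spatial_diffusivity(model: ModelSpec, grid: GridSpec) -> np.ndarray:
    """D(y) entering the x-flux, per phenotype centre."""
    if model.motility.kind == "diffusion":
        return model.motility.coefficient(grid.y_centers)
    if model.motility.kind == "taxis":
        return np.full(grid.ny, model.motility.D_const)
    return np.zeros(grid.ny)  # pressure kind: pure advection in x


def assemble_spatial_flux(
    fld: PhenotypeDensityField, model: ModelSpec, A: np.ndarray
) -> FluxField:
    """Upwind/central interface fluxes F*_{i+1/2,j}; boundary interfaces zero."""
    grid = fld.grid
    n = fld.values
    D = _spatial_diffusivity(model, grid)
    F = np.zeros((grid.nx + 1, grid.ny))
    if grid.nx > 1:
        diff = D[None, :] * (n[1:, :] - n[:-1, :]) / grid.dx
        Ai = A[1:-1, :]
        F[1:-1, :] = diff - np.maximum(Ai, 0.0) * n[:-1, :] - np.minimum(Ai, 0.0) * n[1:, :]
    return FluxField(F_x=F)


def phenotype_term(
    fld: PhenotypeDensityField, transitions, grid: GridSpec
) -> np.ndarray:
    """Per-cell phenotype transition rate C (diffusion stencil + upwinded drift).

    Zero-flux at the phenotype boundaries via ghost reflection; the operator
    sums to zero over each column (conservative) when Abar = 0, and exactly
    as a telescoping flux sum when Abar != 0.
    """
    n = fld.values
    ny = grid.ny
    C = np.zeros_like(n)
    if ny == 1:
        return C
    dy = grid.dy
    Dbar = transitions.Dbar
    if Dbar:
        C[:, 1:-1] = Dbar * (n[:, :-2] - 2 * n[:, 1:-1] + n[:, 2:]) / dy**2
        C[:, 0] = Dbar * (n[:, 1] - n[:, 0]) / dy**2
        C[:, -1] = Dbar * (n[:, -2] - n[:, -1]) / dy**2
    Abar = transitions.Abar
    if Abar:
        # conservative upwind drift: dt n = -d/dy(Abar n), zero boundary fluxes
        G = np.zeros((n.shape[0], ny + 1))  # G_{j+1/2} = (Abar n)* at interfaces
        if Abar > 0:
            G[:, 1:-1] = Abar * n[:, :-1]
        else:
            G[:, 1:-1] = Abar * n[:, 1:]
        C -= np.diff(G, axis=1) / dy
    return C


def _reaction_field(
    model: ModelSpec, grid: GridSpec, rho: np.ndarray, S: np.ndarray | None, P: np.ndarray | None
) -> np.ndarray:
    """R(y_j, rho_i, S_i, P_i) on the grid, shape (nx, ny)."""
    y = grid.y_centers[None, :]
    rho_col = rho[:, None]
    S_col = None if S is None else np.asarray(S, float)[:, None]
    P_col = None if P is None else np.asarray(P, float)[:, None]
    return np.asarray(fitness_eval(model.fitness, y, rho_col, S=S_col, P=P_col), float)


def rhs(
    fld: PhenotypeDensityField, model: ModelSpec, S: np.ndarray | None = None
) -> np.ndarray:
    """Full method-of-lines right-hand side dn/dt = M + C + s n R."""
    grid = fld.grid
    rho = density(fld)
    P = _pressure_profile(model, rho)
    macro = MacroscopicState(rho=rho, ybar=None, mean_y=None, var_y=None, S=S, P=P)
    A = advection_at_interfaces(model, macro, grid)
    F = assemble_spatial_flux(fld, model, A).F_x
    M = np.diff(F, axis=0) / grid.dx
    C = phenotype_term(fld, model.transitions, grid)
    R = _reaction_field(model, grid, rho, S, P)
    return M + C + model.reaction_scale * fld.values * R


# ---------------------------------------------------------------------------
# stability bound and stepping


def cfl_bound(
    model: ModelSpec, fld: PhenotypeDensityField, grid: GridSpec | None = None,
    S: np.ndarray | None = None, cfl_safety: float = 1.0,
) -> float:
    """Largest stable explicit time step: safety * min over the parabolic,
    advective and reaction rates present in the model."""
    grid = grid or fld.grid
    bounds = []
    D = _spatial_diffusivity(model, grid)
    if D.max(initial=0.0) > 0:
        bounds.append(grid.dx**2 / (2.0 * D.max()))
    if grid.ny > 1 and model.transitions.Dbar > 0:
        bounds.append(grid.dy**2 / (2.0 * model.transitions.Dbar))
    if grid.ny > 1 and model.transitions.Abar != 0.0:
        bounds.append(grid.dy / abs(model.transitions.Abar))
    rho = density(fld)
    P = _pressure_profile(model, rho)
    macro = MacroscopicState(rho=rho, ybar=None, mean_y=None, var_y=None, S=S, P=P)
    A = advection_at_interfaces(model, macro, grid)
    amax = np.abs(A).max(initial=0.0)
    if amax > 0:
        bounds.append(grid.dx / amax)
    R = _reaction_field(model, grid, rho, S, P)
    rmax = model.reaction_scale * np.abs(R).max(initial=0.0)
    if rmax > 0:
        bounds.append(1.0 / rmax)
    return cfl_safety * (min(bounds) if bounds else np.inf)


def _frozen_operator(fld, model, rho, S, P):
    """Linear operator v -> M(v) + C(v) + s R v with non-local terms frozen."""
    grid = fld.grid
    macro = MacroscopicState(rho=rho, ybar=None, mean_y=None, var_y=None, S=S, P=P)
    A = advection_at_interfaces(model, macro, grid)
    R = _reaction_field(model, grid, rho, S, P)
    D = _spatial_diffusivity(model, grid)
    scale = model.reaction_scale

    def apply(v: np.ndarray) -> np.ndarray:
        tmp = PhenotypeDensityField(grid, v, fld.time)
        F = np.zeros((grid.nx + 1, grid.ny))
        if grid.nx > 1:
            diff = D[None, :] * (v[1:, :] - v[:-1, :]) / grid.dx
            Ai = A[1:-1, :]
            F[1:-1, :] = diff - np.maximum(Ai, 0.0) * v[:-1, :] - np.minimum(Ai, 0.0) * v[1:, :]
        M = np.diff(F, axis=0) / grid.dx
        C = phenotype_term(tmp, model.transitions, grid)
        return M + C + scale * v * R

    return apply


def _step_signal(S: np.ndarray, sig: SignalSpec, rho: np.ndarray, dx: float, dt: float) -> np.ndarray:
    if sig.mode != "reaction_diffusion":
        return S
    S_new = S + dt * signal_rhs(sig, S, rho, dx)
    return np.maximum(S_new, 0.0)


def initial_signal(model: ModelSpec, grid: GridSpec) -> np.ndarray | None:
    if model.signal is None:
        return None
    if model.signal.mode == "static_profile":
        return np.asarray(as_profile(model.signal.Sigma_of_x)(grid.x_centers), float)
    return np.full(grid.nx, model.signal.S_init, float)


def step(
    fld: PhenotypeDensityField,
    model: ModelSpec,
    integrator: IntegratorSpec,
    S: np.ndarray | None = None,
) -> tuple[PhenotypeDensityField, np.ndarray | None]:
    """Advance one time step; returns the new field and (possibly updated) S.

    A coupled dynamic signal is integrated by first-order operator splitting
    on the same time grid: S-step with the pre-step density, then n-step.
    """
    dt = integrator.dt
    grid = fld.grid
    if model.signal is not None and S is None:
        S = initial_signal(model, grid)
    rho0 = density(fld)
    if model.signal is not None and model.signal.mode == "reaction_diffusion":
        S = _step_signal(S, model.signal, rho0, grid.dx, dt)

    if integrator.scheme == "explicit_euler":
        bound = cfl_bound(model, fld, grid, S=S, cfl_safety=integrator.cfl_safety)
        if dt > bound:
            raise IntegrationError(
                f"explicit step dt={dt:g} exceeds stability bound {bound:g}; "
                "reduce dt or use an implicit/IMEX scheme"
            )
        new_vals = fld.values + dt * rhs(fld, model, S=S)
    elif integrator.scheme == "imex":
        rho = rho0
        P = _pressure_profile(model, rho)
        macro = MacroscopicState(rho=rho, ybar=None, mean_y=None, var_y=None, S=S, P=P)
        A = advection_at_interfaces(model, macro, grid)
        # transport (and phenotype diffusion) remain explicit: enforce their bound
        tb = []
        D = _spatial_diffusivity(model, grid)
        if D.max(initial=0.0) > 0:
            tb.append(grid.dx**2 / (2.0 * D.max()))
        if grid.ny > 1 and model.transitions.Dbar > 0:
            tb.append(grid.dy**2 / (2.0 * model.transitions.Dbar))
        amax = np.abs(A).max(initial=0.0)
        if amax > 0:
            tb.append(grid.dx / amax)
        if tb and dt > integrator.cfl_safety * min(tb):
            raise IntegrationError(
                f"IMEX step dt={dt:g} exceeds the explicit transport bound "
                f"{integrator.cfl_safety * min(tb):g}; reduce dt"
            )
        F = assemble_spatial_flux(fld, model, A).F_x
        M = np.diff(F, axis=0) / grid.dx
        C = phenotype_term(fld, model.transitions, grid)
        R = model.reaction_scale * _reaction_field(model, grid, rho, S, P)
        Rpos = np.maximum(R, 0.0)
        Rneg = np.minimum(R, 0.0)
        new_vals = (fld.values + dt * (M + C + fld.values * Rpos)) / (1.0 - dt * Rneg)
    else:  # implicit_euler, Picard-lagged non-local terms
        n_old = fld.values
        guess = n_old.copy()
        shape = n_old.shape
        size = n_old.size
        converged = False
        for _ in range(integrator.picard_maxiter):
            tmp = PhenotypeDensityField(grid, guess, fld.time)
            rho = density(tmp)
            P = _pressure_profile(model, rho)
            L = _frozen_operator(fld, model, rho, S, P)
            op = LinearOperator(
                (size, size),
                matvec=lambda v: v - dt * L(v.reshape(shape)).ravel(),
            )
            sol, info = lgmres(op, n_old.ravel(), x0=guess.ravel(),
                               rtol=integrator.linear_tol, atol=0.0, maxiter=2000)
            if info != 0:
                raise IntegrationError(f"implicit linear solve failed (lgmres info={info})")
            sol = sol.reshape(shape)
            delta = np.abs(sol - guess).max()
            guess = sol
            ref = max(np.abs(guess).max(), 1.0)
            if delta <= integrator.picard_tol * ref:
                converged = True
                break
        if not converged:
            raise IntegrationError(
                f"implicit step did not converge in {integrator.picard_maxiter} Picard iterations "
                f"(last update {delta:.3e})"
            )
        new_vals = guess

    out = PhenotypeDensityField(grid, new_vals, fld.time + dt)
    out.validate()
    return out, S


@dataclass
class SimulationResult:
    """Saved snapshots and macroscopic series from :func:`simulate`."""

    grid: GridSpec
    times: np.ndarray  # saved times
    fields: list  # PhenotypeDensityField at saved times
    rho_series: np.ndarray  # (n_saved, nx)
    macros: list  # MacroscopicState at saved times
    signals: list  # S profiles (or None) at saved times
    mass: np.ndarray  # total mass ledger at saved times
    min_n: np.ndarray  # min density at saved times
    dt: float  # time step actually used


def simulate(
    model: ModelSpec,
    initial: PhenotypeDensityField,
    T: float,
    integrator: IntegratorSpec,
    save_times=None,
) -> SimulationResult:
    """Run the method-of-lines solve to time T, saving requested snapshots.

    ``save_times`` are snapped to the uniform step grid; the initial state is
    always included.  Mass and the minimum of n are recorded per snapshot.
    """
    if T <= 0:
        raise ConfigurationError("final time T must be positive")
    dt = integrator.dt
    n_steps = int(round(T / dt))
    if abs(n_steps * dt - T) > 1e-9 * max(T, 1.0):
        n_steps = int(np.ceil(T / dt))
    if save_times is None:
        save_times = [0.0, T]
    save_steps = sorted({min(int(round(t / dt)), n_steps) for t in save_times} | {0})

    fld = initial.copy()
    S = initial_signal(model, fld.grid)
    fields, macros, signals, times, mass, min_n = [], [], [], [], [], []

    def record(f, s):
        fields.append(f.copy())
        m = macroscopic_state(f, S=None if s is None else s.copy(),
                              P=_pressure_profile(model, density(f)))
        macros.append(m)
        signals.append(None if s is None else s.copy())
        times.append(f.time)
        mass.append(f.mass)
        min_n.append(float(f.values.min()))

    if 0 in save_steps:
        record(fld, S)
    for k in range(1, n_steps + 1):
        fld, S = step(fld, model, integrator, S=S)
        if k in save_steps:
            record(fld, S)
    return SimulationResult(
        grid=fld.grid,
        times=np.asarray(times),
        fields=fields,
        rho_series=np.vstack([density(f) for f in fields]),
        macros=macros,
        signals=signals,
        mass=np.asarray(mass),
        min_n=np.asarray(min_n),
        dt=dt,
    )
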