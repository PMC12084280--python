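"""Space-free selection-mutation dynamics and the Gaussian moment oracle.

The non-local PDE

    dn/dt = Dbar d2n/dy2 + n R(y, rho),   rho(t) = int n dy,

with the single-peak quadratic fitness R = gamma - (y - phi)^2 - kappa*rho
and a Gaussian initial profile admits an exact Gaussian solution whose
weight rho(t), mean ybar(t) and inverse variance v(t) = 1/sigma^2(t) obey

    dv/dt    = 2 (1 - Dbar v^2)
    dybar/dt = (2/v) (phi - ybar)
    drho/dt  = { [gamma - 1/v - (ybar - phi)^2] - kappa rho } rho.

Under the small-mutation scaling (Dbar = eps^2, t -> t/eps, initial
variance eps) the solution stays a Gaussian of variance eps whose mean
follows the canonical equation dybar/dt = 2(phi - ybar) and whose weight
relaxes to the root of R(ybar, rho) = 0; as eps -> 0 the phenotype density
concentrates into a weighted Dirac mass (a monomorphic population).  This
module integrates the moment ODEs to high accuracy (the analytical oracle),
solves the PDE itself with the shared method-of-lines machinery, and
provides the WKB transform u = eps*log(n) and concentration diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .grids import ConfigurationError, PhenotypeDensityField, make_grid
from .models import FitnessSpec, MotilitySpec, ModelSpec, PhenotypeTransitionSpec, fitness_eval
from .profiles import constant
from .solver import IntegratorSpec, simulate

__all__ = [
    "GaussianMomentState",
    "EpsilonScaling",
    "MomentTrajectory",
    "moment_ode_solve",
    "moment_ode_solve_rescaled",
    "gaussian_density",
    "nonlocal_model",
    "simulate_nonlocal",
    "NonlocalTrajectory",
    "wkb_transform",
    "inverse_wkb",
    "concentration_check",
    "canonical_rate",
]

NEG_INF = -np.inf


@dataclass
class GaussianMomentState:
    """(rho, ybar, v) of a Gaussian phenotype density; v = 1/sigma^2 > 0."""

    rho: float
    ybar: float
    v: float
    time: float = 0.0

    def __post_init__(self):
        if self.rho < 0 or self.v <= 0:
            raise ConfigurationError("need rho >= 0 and v > 0")

    @property
    def variance(self) -> float:
        return 1.0 / self.v


@dataclass(frozen=True)
class EpsilonScaling:
    """Small-parameter scaling: time/space by 1/eps, Dbar = eps^2, sigma0^2 = eps."""

    epsilon: float
    scale_time_space: bool = True
    scale_mutation: bool = True
    scale_initial_variance: bool = True

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ConfigurationError("epsilon must be positive")


@dataclass
class MomentTrajectory:
    t: np.ndarray
    rho: np.ndarray
    ybar: np.ndarray
    v: np.ndarray

    @property
    def variance(self) -> np.ndarray:
        return 1.0 / self.v

    def final(self) -> GaussianMomentState:
        return GaussianMomentState(float(self.rho[-1]), float(self.ybar[-1]), float(self.v[-1]), float(self.t[-1]))


def _require_quadratic(fitness: FitnessSpec) -> None:
    if fitness.form != "quadratic":
        raise ConfigurationError("the Gaussian moment oracle requires the quadratic fitness form")


def moment_ode_solve(
    fitness: FitnessSpec,
    Dbar: float,
    init: GaussianMomentState,
    T: float,
    t_eval=None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> MomentTrajectory:
    """Integrate the (v, ybar, rho) moment ODEs with tight tolerances.

    Serves as ground truth for the PDE solver on Gaussian initial data.
    """
    _require_quadratic(fitness)
    g, phi, kap = fitness.gamma, fitness.phi, fitness.kappa

    def f(t, s):
        v, ybar, rho = s
        return [
            2.0 * (1.0 - Dbar * v**2),
            (2.0 / v) * (phi - ybar),
            ((g - 1.0 / v - (ybar - phi) ** 2) - kap * rho) * rho,
        ]

    if t_eval is None:
        t_eval = np.linspace(0.0, T, 201)
    sol = solve_ivp(f, (0.0, T), [init.v, init.ybar, init.rho], t_eval=t_eval,
                    method="RK45", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"moment ODE integration failed: {sol.message}")
    return MomentTrajectory(t=sol.t, v=sol.y[0], ybar=sol.y[1], rho=sol.y[2])


def moment_ode_solve_rescaled(
    fitness: FitnessSpec,
    epsilon: float,
    rho0: float,
    ybar0: float,
    T: float,
    t_eval=None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> MomentTrajectory:
    """Moment ODEs in the small-mutation scaling: variance pinned at eps,

        dybar/dt = 2 (phi - ybar),
        eps drho/dt = { [gamma - eps - (ybar - phi)^2] - kappa rho } rho.
    """
    _require_quadratic(fitness)
    g, phi, kap = fitness.gamma, fitness.phi, fitness.kappa

    def f(t, s):
        ybar, rho = s
        return [
            2.0 * (phi - ybar),
            ((g - epsilon - (ybar - phi) ** 2) - kap * rho) * rho / epsilon,
        ]

    if t_eval is None:
        t_eval = np.linspace(0.0, T, 201)
    sol = solve_ivp(f, (0.0, T), [ybar0, rho0], t_eval=t_eval, method="LSODA",
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"rescaled moment ODE integration failed: {sol.message}")
    v = np.full_like(sol.t, 1.0 / epsilon)
    return MomentTrajectory(t=sol.t, v=v, ybar=sol.y[0], rho=sol.y[1])


def gaussian_density(state: GaussianMomentState, y: np.ndarray) -> np.ndarray:
    """Weighted Gaussian profile with weight rho, mean ybar, variance 1/v."""
    y = np.asarray(y, float)
    var = state.variance
    return state.rho / np.sqrt(2.0 * np.pi * var) * np.exp(-((y - state.ybar) ** 2) / (2.0 * var))


# ---------------------------------------------------------------------------
# PDE solve on a 1D phenotype grid (shared MOL machinery, nx = 1)


def nonlocal_model(fitness: FitnessSpec, Dbar: float | None = None,
                   scaling: EpsilonScaling | None = None) -> ModelSpec:
    """ModelSpec for the space-free equation; with an EpsilonScaling the
    rescaled form dt n = eps d2n/dy2 + n R / eps is produced."""
    if scaling is not None:
        eps = scaling.epsilon
        Dbar_eff = eps if scaling.scale_mutation and scaling.scale_time_space else scaling.epsilon**2
        scale = 1.0 / eps if scaling.scale_time_space else 1.0
    else:
        if Dbar is None:
            raise ConfigurationError("provide Dbar or an EpsilonScaling")
        Dbar_eff, scale = Dbar, 1.0
    return ModelSpec(
        motility=MotilitySpec(kind="diffusion", D_of_y=constant(0.0)),
        fitness=fitness,
        transitions=PhenotypeTransitionSpec(Dbar=Dbar_eff),
        reaction_scale=scale,
        name="nonlocal",
    )


@dataclass
class NonlocalTrajectory:
    """Phenotype-density trajectory n(t, y) with its moment series."""

    t: np.ndarray
    y: np.ndarray
    profiles: np.ndarray  # (nt, ny)
    rho: np.ndarray
    mean_y: np.ndarray
    var_y: np.ndarray
    epsilon: float | None = None

    @property
    def dy(self) -> float:
        return float(self.y[1] - self.y[0]) if self.y.size > 1 else 1.0


def _moments_1d(profiles: np.ndarray, y: np.ndarray, dy: float):
    rho = dy * profiles.sum(axis=1)
    safe = np.where(rho > 0, rho, 1.0)
    mean = dy * (profiles * y).sum(axis=1) / safe
    var = dy * (profiles * (y[None, :] - mean[:, None]) ** 2).sum(axis=1) / safe
    return rho, mean, np.maximum(var, 0.0)


def simulate_nonlocal(
    fitness: FitnessSpec,
    initial: np.ndarray,
    T: float,
    y_grid: np.ndarray,
    Dbar: float | None = None,
    scaling: EpsilonScaling | None = None,
    integrator: IntegratorSpec | str = "rk45",
    save_times=None,
    rtol: float = 1e-8,
) -> NonlocalTrajectory:
    """Solve the selection-mutation PDE on a bounded phenotype interval.

    The unbounded trait axis is truncated to the supplied grid with
    zero-flux ends; callers should check the boundary mass stays negligible.
    ``integrator`` may be an :class:`IntegratorSpec` (fixed-step schemes) or
    ``"rk45"``/``"lsoda"`` for adaptive integration of the MOL system.
    """
    y = np.asarray(y_grid, float)
    ny = y.size
    dy = y[1] - y[0]
    grid = make_grid(0.0, 1.0, 1, y[0] - dy / 2, y[-1] + dy / 2, ny)
    model = nonlocal_model(fitness, Dbar=Dbar, scaling=scaling)
    initial = np.asarray(initial, float)
    if initial.shape != (ny,):
        raise ConfigurationError("initial profile must live on the supplied y grid")
    if save_times is None:
        save_times = np.linspace(0.0, T, 61)
    save_times = np.asarray(save_times, float)

    if isinstance(integrator, IntegratorSpec):
        fld = PhenotypeDensityField(grid, initial[None, :])
        res = simulate(model, fld, T, integrator, save_times=list(save_times))
        t = res.times
        profiles = np.vstack([f.values[0] for f in res.fields])
    else:
        from .solver import rhs as mol_rhs

        def f(t, nflat):
            fld = PhenotypeDensityField(grid, np.asarray(nflat).reshape(1, ny), t)
            return mol_rhs(fld, model).ravel()

        sol = solve_ivp(f, (0.0, T), initial, t_eval=save_times,
                        method="RK45" if integrator == "rk45" else "LSODA",
                        rtol=rtol, atol=1e-12)
        if not sol.success:
            raise RuntimeError(f"non-local PDE integration failed: {sol.message}")
        t = sol.t
        profiles = sol.y.T.copy()

    rho, mean, var = _moments_1d(profiles, y, dy)
    return NonlocalTrajectory(
        t=t, y=y, profiles=profiles, rho=rho, mean_y=mean, var_y=var,
        epsilon=None if scaling is None else scaling.epsilon,
    )


# ---------------------------------------------------------------------------
# WKB / concentration diagnostics


def wkb_transform(profile: np.ndarray, epsilon: float) -> np.ndarray:
    """Hopf-Cole / WKB transform u = eps * log(n); zeros map to -inf."""
    profile = np.asarray(profile, float)
    if np.any(profile < 0):
        raise ValueError("WKB transform requires a non-negative profile")
    with np.errstate(divide="ignore"):
        return np.where(profile > 0.0, epsilon * np.log(profile, where=profile > 0.0,
                                                        out=np.zeros_like(profile)), NEG_INF)


def inverse_wkb(u: np.ndarray, epsilon: float) -> np.ndarray:
    u = np.asarray(u, float)
    return np.where(np.isneginf(u), 0.0, np.exp(u / epsilon))


@dataclass
class ConcentrationReport:
    """Per-time concentration diagnostics of a rescaled trajectory.

    ``max_u`` -> 0, ``variance`` -> 0, and ``weight_residual`` = |R(ybar,
    rho)| -> 0 are the numerical signatures of Dirac concentration with the
    weight pinned by the zero-fitness relation.
    """

    t: np.ndarray
    max_u: np.ndarray
    variance: np.ndarray
    weight_residual: np.ndarray


def concentration_check(traj: NonlocalTrajectory, fitness: FitnessSpec) -> ConcentrationReport:
    if traj.epsilon is None:
        raise ConfigurationError("concentration diagnostics need a rescaled (epsilon) trajectory")
    eps = traj.epsilon
    # adaptive integrators can leave O(round-off) negative undershoots; treat
    # anything below the relative floor as empty rather than failing the log
    floor = 1e-13 * max(traj.profiles.max(), 1.0)
    clipped = np.where(traj.profiles > floor, traj.profiles, 0.0)
    max_u = np.array([
        wkb_transform(p, eps).max() if p.max() > 0 else NEG_INF for p in clipped
    ])
    resid = np.abs(np.asarray(fitness_eval(fitness, traj.mean_y, traj.rho), float))
    return ConcentrationReport(t=traj.t, max_u=max_u, variance=traj.var_y, weight_residual=resid)


def canonical_rate(traj: NonlocalTrajectory, phi: float, fit_window: tuple[float, float] | None = None) -> float:
    """Fitted exponential relaxation rate of (phi - ybar(t)).

    The canonical equation predicts rate 2 in the rescaled model.
    """
    gap = np.abs(phi - traj.mean_y)
    mask = gap > 1e-12
    if fit_window is not None:
        mask &= (traj.t >= fit_window[0]) & (traj.t <= fit_window[1])
    if mask.sum() < 3:
        raise ValueError("not enough usable points to fit a relaxation rate")
    slope = np.polyfit(traj.t[mask], np.log(gap[mask]), 1)[0]
    return float(-slope)
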