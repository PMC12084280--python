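"""On-lattice branching random walk for phenotype-structured populations.

Each agent occupies a node of a space x phenotype lattice.  Per time step of
length tau, every cell independently

  1. divides (two identical daughters at the same node, probability
     tau*rP), dies (probability tau*rD), or stays quiescent;
  2. survivors and daughters move one node left/right in space with
     probabilities PLx/PRx (or stay);
  3. then switch one node down/up in phenotype with constant probabilities
     pLy/pRy (or stay).

Moves off the lattice are aborted (the cell stays), the discrete analogue of
zero-flux boundaries.  The density read-outs are n = N/(hx*hy) and
rho = hy * sum_j n.  In the diffusive limit hx, hy, tau -> 0 with
hx^2/(2 tau) -> alpha_x and hy^2/(2 tau) -> alpha_y the ensemble dynamics
follow the corresponding phenotype-structured PDE with

    D_x = alpha_x * (PLx + PRx),      A_x = -alpha_x * (Psi_x + dPhi_x/dx),
    Dbar = alpha_y * (pLy + pRy),     Abar = -alpha_y * psi_y,

where PLx - PRx = (hx/2) Psi_x and PLx + PRx = Phi_x at leading order.
:func:`probabilities_from_target` inverts these relations so that an ABM run
can be matched against a continuum solve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import ConfigurationError, GridSpec, PhenotypeDensityField
from .models import ModelSpec, pressure_eval
from .profiles import as_profile

__all__ = [
    "ABMConfig",
    "ABMState",
    "ScalingMap",
    "abm_step",
    "abm_simulate",
    "probabilities_from_target",
    "ensemble_mean_density",
]


@dataclass(frozen=True)
class ScalingMap:
    """Diffusive-limit scale factors linking lattice steps to PDE rates."""

    hx: float
    hy: float
    tau: float

    @property
    def alpha_x(self) -> float:
        return self.hx**2 / (2.0 * self.tau)

    @property
    def alpha_y(self) -> float:
        return self.hy**2 / (2.0 * self.tau)


@dataclass
class ABMConfig:
    """Lattice geometry, per-step probabilities and per-capita rates.

    ``PLx``/``PRx`` are callables ``(t, x, y, rho) -> (nx, ny) array`` (rho
    is the current density profile, enabling pressure-coupled movement);
    ``rP``/``rD`` are callables ``(t, x, y, rho) -> (nx, ny) array`` of
    proliferation and death rates.  ``pLy``/``pRy`` are constants.
    """

    grid: GridSpec  # lattice nodes = grid cell centres
    tau: float
    PLx: object = None
    PRx: object = None
    pLy: float = 0.0
    pRy: float = 0.0
    rP: object = None
    rD: object = None
    seed: int | None = None

    def __post_init__(self):
        if self.tau <= 0:
            raise ConfigurationError("tau must be positive")
        if self.pLy < 0 or self.pRy < 0 or self.pLy + self.pRy > 1:
            raise ConfigurationError("need pLy, pRy >= 0 and pLy + pRy <= 1")

    @property
    def hx(self) -> float:
        return self.grid.dx

    @property
    def hy(self) -> float:
        return self.grid.dy

    @property
    def scaling(self) -> ScalingMap:
        return ScalingMap(self.hx, self.hy, self.tau)


@dataclass
class ABMState:
    """Integer occupancy over the lattice plus the RNG driving the walk."""

    N: np.ndarray  # (nx, ny) integer counts
    k: int  # step counter
    rng: np.random.Generator
    config: ABMConfig

    @property
    def time(self) -> float:
        return self.k * self.config.tau

    def density_field(self) -> PhenotypeDensityField:
        vals = self.N / (self.config.hx * self.config.hy)
        return PhenotypeDensityField(self.config.grid, vals.astype(float), self.time)

    def rho(self) -> np.ndarray:
        return self.config.hy * (self.N / (self.config.hx * self.config.hy)).sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.N.sum())


def _eval_prob(f, t, grid: GridSpec, rho: np.ndarray) -> np.ndarray:
    if f is None:
        return np.zeros(grid.shape)
    out = np.asarray(f(t, grid.x_centers[:, None], grid.y_centers[None, :], rho), float)
    return np.broadcast_to(out, grid.shape)


def _validate_probs(name: str, *ps):
    tot = sum(ps)
    bad = (tot > 1.0 + 1e-12) | np.any([p < -1e-15 for p in ps], axis=0)
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise ConfigurationError(
            f"{name} probabilities invalid at lattice site ({i}, {j}): "
            f"values {[np.asarray(p)[i, j] for p in ps]} (sum must lie in [0, 1])"
        )


def abm_step(state: ABMState, config: ABMConfig | None = None) -> ABMState:
    """Advance the branching random walk by one step (synchronous update).

    Division/death are resolved first (with rho from the pre-step occupancy),
    then movement, then phenotype switching; daughters participate in the
    movement and switching of the same step like any other cell.
    """
    cfg = config or state.config
    rng = state.rng
    grid = cfg.grid
    t = state.time
    N = state.N
    rho = state.rho()

    # --- proliferation / death
    PP = cfg.tau * _eval_prob(cfg.rP, t, grid, rho)
    PD = cfg.tau * _eval_prob(cfg.rD, t, grid, rho)
    _validate_probs("proliferation/death", PP, PD)
    flatN = N.ravel()
    pvals = np.stack([PP.ravel(), PD.ravel(), 1.0 - PP.ravel() - PD.ravel()], axis=-1)
    draws = rng.multinomial(flatN, np.clip(pvals, 0.0, 1.0))
    divides, dies = draws[:, 0], draws[:, 1]
    N = (flatN + divides - dies).reshape(grid.shape)

    # --- spatial movement
    PL = _eval_prob(cfg.PLx, t, grid, rho)
    PR = _eval_prob(cfg.PRx, t, grid, rho)
    _validate_probs("movement", PL, PR)
    pv = np.stack([PL.ravel(), PR.ravel(), 1.0 - PL.ravel() - PR.ravel()], axis=-1)
    mv = rng.multinomial(N.ravel(), np.clip(pv, 0.0, 1.0))
    left = mv[:, 0].reshape(grid.shape)
    right = mv[:, 1].reshape(grid.shape)
    stay = mv[:, 2].reshape(grid.shape)
    new = stay.copy()
    new[:-1, :] += left[1:, :]
    new[0, :] += left[0, :]  # aborted move off the left edge
    new[1:, :] += right[:-1, :]
    new[-1, :] += right[-1, :]  # aborted move off the right edge
    N = new

    # --- phenotype switching
    if grid.ny > 1 and (cfg.pLy > 0 or cfg.pRy > 0):
        pv = np.array([cfg.pLy, cfg.pRy, 1.0 - cfg.pLy - cfg.pRy])
        sw = rng.multinomial(N.ravel(), pv).reshape(grid.shape + (3,))
        down, up, staying = sw[..., 0], sw[..., 1], sw[..., 2]
        new = staying.copy()
        new[:, :-1] += down[:, 1:]
        new[:, 0] += down[:, 0]
        new[:, 1:] += up[:, :-1]
        new[:, -1] += up[:, -1]
        N = new

    return ABMState(N=N, k=state.k + 1, rng=rng, config=cfg)


def abm_simulate(config: ABMConfig, T: float, record_times=None,
                 initial: np.ndarray | None = None, seed: int | None = None):
    """Run the ABM to time T; returns (times, list of density fields, final state).

    ``T`` must be an integer number of steps tau.  Every run is driven by an
    explicit seed (from ``seed`` or ``config.seed``); identical seeds give
    bit-identical trajectories.
    """
    K = int(round(T / config.tau))
    if abs(K * config.tau - T) > 1e-9 * max(T, 1.0):
        raise ConfigurationError("T must be an integer multiple of tau")
    use_seed = seed if seed is not None else config.seed
    if use_seed is None:
        raise ConfigurationError("ABM runs require an explicit RNG seed")
    rng = np.random.default_rng(use_seed)
    if initial is None:
        raise ConfigurationError("an initial occupancy map is required")
    N0 = np.asarray(initial)
    if N0.shape != config.grid.shape or not np.issubdtype(N0.dtype, np.integer):
        raise ConfigurationError("initial occupancy must be an integer array on the lattice")
    state = ABMState(N=N0.copy(), k=0, rng=rng, config=config)

    if record_times is None:
        record_times = [0.0, T]
    record_steps = sorted({min(int(round(ts / config.tau)), K) for ts in record_times} | {0})
    record_set = set(record_steps)

    times, fields = [], []
    if 0 in record_set:
        times.append(0.0)
        fields.append(state.density_field())
    for k in range(1, K + 1):
        state = abm_step(state)
        if k in record_set:
            times.append(state.time)
            fields.append(state.density_field())
    return np.asarray(times), fields, state


def probabilities_from_target(model: ModelSpec, hx: float, hy: float, tau: float,
                              grid: GridSpec | None = None, seed: int | None = None) -> ABMConfig:
    """Invert the diffusive-limit expansions so the ABM matches a ModelSpec.

    diffusion kind:  PL = PR = D(y) / (2 alpha_x)
    pressure kind:   PL - PR = (hx / alpha_x) * mu(y) * dP/dx, PL + PR = 0+
                     (drift-only movement, probabilities split around 0)
    taxis kind:      PL + PR = D / alpha_x, PL - PR = -(hx / alpha_x) chi(y) dS/dx
    phenotype:       pLy = pRy = Dbar / (2 alpha_y)  (for Abar = 0).

    Raises if any implied probability leaves [0, 1] on the lattice.
    """
    if grid is None:
        raise ConfigurationError("supply the lattice grid")
    if abs(grid.dx - hx) > 1e-12 or (grid.ny > 1 and abs(grid.dy - hy) > 1e-12):
        raise ConfigurationError("lattice steps must match the grid spacing")
    sc = ScalingMap(hx, hy, tau)
    ax, ay = sc.alpha_x, sc.alpha_y
    y = grid.y_centers

    trans = model.transitions
    if trans.Abar != 0.0:
        psi_y = -trans.Abar / ay
        phi_y = trans.Dbar / ay
        pLy = (phi_y + (hy / 2) * psi_y) / 2.0
        pRy = (phi_y - (hy / 2) * psi_y) / 2.0
    else:
        pLy = pRy = trans.Dbar / (2.0 * ay) if grid.ny > 1 else 0.0
    if pLy < 0 or pRy < 0 or pLy + pRy > 1:
        raise ConfigurationError(
            f"phenotype-switch probabilities ({pLy:.3g}, {pRy:.3g}) leave [0,1]; reduce hy or tau"
        )

    kind = model.motility.kind
    if kind == "diffusion":
        Phi = model.motility.coefficient(y) / ax  # Phi_x(y) = D(y)/alpha_x
        if Phi.max(initial=0.0) > 1.0:
            raise ConfigurationError("implied movement probabilities exceed 1; reduce hx or tau")

        def PLx(t, x, yy, rho, Phi=Phi):
            return np.broadcast_to(Phi[None, :] / 2.0, (grid.nx, grid.ny))

        PRx = PLx
    elif kind == "pressure":
        muv = model.motility.coefficient(y)
        law = model.pressure

        def _drift(t, x, yy, rho, sign):
            P = np.asarray(pressure_eval(law, rho), float)
            dP = np.gradient(P, hx)
            psi = muv[None, :] * dP[:, None] / ax  # Psi_x = mu_hat dP/dx, mu_hat = mu/alpha_x
            p = sign * (hx / 4.0) * psi
            return np.clip(p, 0.0, None)

        def PLx(t, x, yy, rho):
            return _drift(t, x, yy, rho, +1.0)

        def PRx(t, x, yy, rho):
            return _drift(t, x, yy, rho, -1.0)
    else:  # taxis (needs a frozen signal profile)
        if model.signal is None or model.signal.mode != "static_profile":
            raise ConfigurationError("taxis-target ABM requires a static signal profile")
        chiv = model.motility.coefficient(y)
        Sigma = np.asarray(as_profile(model.signal.Sigma_of_x)(grid.x_centers), float)
        dS = np.gradient(Sigma, hx)
        Phi0 = model.motility.D_const / ax

        def PLx(t, x, yy, rho):
            psi = -chiv[None, :] * dS[:, None] / ax
            return np.clip(Phi0 / 2.0 + (hx / 4.0) * psi, 0.0, None)

        def PRx(t, x, yy, rho):
            psi = -chiv[None, :] * dS[:, None] / ax
            return np.clip(Phi0 / 2.0 - (hx / 4.0) * psi, 0.0, None)

    fit = model.fitness
    scale = model.reaction_scale

    def rP(t, x, yy, rho):
        from .models import fitness_eval

        P = None if model.pressure is None else pressure_eval(model.pressure, rho)
        R = np.asarray(
            fitness_eval(fit, yy, rho[:, None] if np.ndim(rho) == 1 else rho,
                         P=None if P is None else np.asarray(P)[:, None]),
            float,
        ) * scale
        return np.broadcast_to(np.maximum(R, 0.0), (grid.nx, grid.ny))

    def rD(t, x, yy, rho):
        from .models import fitness_eval

        P = None if model.pressure is None else pressure_eval(model.pressure, rho)
        R = np.asarray(
            fitness_eval(fit, yy, rho[:, None] if np.ndim(rho) == 1 else rho,
                         P=None if P is None else np.asarray(P)[:, None]),
            float,
        ) * scale
        return np.broadcast_to(np.maximum(-R, 0.0), (grid.nx, grid.ny))

    return ABMConfig(grid=grid, tau=tau, PLx=PLx, PRx=PRx, pLy=pLy, pRy=pRy,
                     rP=rP, rD=rD, seed=seed)


def ensemble_mean_density(config: ABMConfig, T: float, initial: np.ndarray,
                          n_seeds: int, base_seed: int, record_times=None):
    """Ensemble mean of rho over independently seeded runs.

    Child seeds are spawned deterministically from ``base_seed``.  Returns
    (times, mean rho array of shape (nt, nx)).
    """
    ss = np.random.SeedSequence(base_seed)
    children = ss.spawn(n_seeds)
    acc = None
    times = None
    for child in children:
        seed = int(child.generate_state(1)[0] % (2**31 - 1))
        t, fields, _ = abm_simulate(config, T, record_times=record_times,
                                    initial=initial, seed=seed)
        rhos = np.vstack([config.grid.dy * f.values.sum(axis=1) for f in fields])
        acc = rhos if acc is None else acc + rhos
        times = t
    return times, acc / n_seeds
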