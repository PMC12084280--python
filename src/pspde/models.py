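"""Declarative model specifications and evaluators.

A :class:`ModelSpec` describes one phenotype-structured PDE instance:

    dn/dt = transport in x  +  transitions in y  +  n * R * reaction_scale

where the transport mechanism is one of

  - ``diffusion``: flux D(y) dn/dx,
  - ``pressure``:  advection with velocity -mu(y) dP/dx, P = Pi(rho),
  - ``taxis``:     advection with velocity chi(y) dS/dx plus constant
                   diffusion D dn/dx,

phenotype transitions are diffusion (rate Dbar) plus an optional constant
drift Abar, and the fitness R is the net per-capita growth rate.  The
``reaction_scale`` carries the 1/epsilon factor of the sharp-front /
small-mutation rescalings so the fitness functions themselves stay O(1).

Presets encode the model families studied in the source literature on
travelling waves and phenotypic concentration: the Fisher-KPP equation, a
motility/proliferation trade-off with phenotypic diffusion, the cane-toad
dispersal model, the non-local selection-mutation model, and go-or-grow
pressure and chemotaxis models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import ConfigurationError
from .profiles import as_profile, constant, linear

__all__ = [
    "MotilitySpec",
    "FitnessSpec",
    "PressureLaw",
    "SignalSpec",
    "PhenotypeTransitionSpec",
    "ModelSpec",
    "fitness_eval",
    "pressure_eval",
    "inverse_pressure",
    "signal_rhs",
    "preset",
    "PRESETS",
]


@dataclass(frozen=True)
class MotilitySpec:
    """Movement mechanism and its phenotype-dependent coefficients."""

    kind: str  # diffusion | pressure | taxis
    D_of_y: object | None = None  # spatial diffusivity D(y), diffusion kind
    mu_of_y: object | None = None  # mobility mu(y), pressure kind
    chi_of_y: object | None = None  # tactic sensitivity chi(y), taxis kind
    D_const: float = 0.0  # constant diffusivity alongside taxis

    def __post_init__(self):
        if self.kind not in ("diffusion", "pressure", "taxis"):
            raise ConfigurationError(f"unknown motility kind {self.kind!r}")
        required = {"diffusion": "D_of_y", "pressure": "mu_of_y", "taxis": "chi_of_y"}[self.kind]
        if getattr(self, required) is None:
            raise ConfigurationError(f"motility kind {self.kind!r} requires {required}")
        forbidden = {"diffusion": ("mu_of_y", "chi_of_y"), "pressure": ("D_of_y", "chi_of_y"), "taxis": ("mu_of_y",)}
        for name in forbidden[self.kind]:
            if getattr(self, name) is not None:
                raise ConfigurationError(f"motility kind {self.kind!r} must not set {name}")
        if self.kind != "taxis" and self.D_const:
            raise ConfigurationError("D_const is only meaningful for the taxis kind")

    def coefficient(self, y: np.ndarray) -> np.ndarray:
        """Evaluate the kind's y-dependent coefficient on phenotype centres."""
        f = as_profile({"diffusion": self.D_of_y, "pressure": self.mu_of_y, "taxis": self.chi_of_y}[self.kind])
        vals = np.asarray(f(np.asarray(y, float)), float)
        if np.any(~np.isfinite(vals)) or np.any(vals < 0):
            raise ConfigurationError(f"{self.kind} coefficient must be finite and non-negative on the phenotype domain")
        return vals


@dataclass(frozen=True)
class FitnessSpec:
    """Net per-capita growth (fitness) function R.

    forms:
      - ``quadratic``:        R = gamma - (y - phi)^2 - kappa * rho
      - ``go_or_grow_linear``: R = r(y) - kappa * rho
      - ``logistic_uniform``: R = gamma * (1 - rho / rho_M)   (no y dependence)
      - ``env_quadratic``:    R = g(S) - (y - f(S))^2 - kappa * rho
      - ``pressure_linear``:  R = r(y) - kappa * P
    """

    form: str
    gamma: float = 1.0
    phi: float = 0.0
    kappa: float = 1.0
    r_of_y: object | None = None
    rho_M: float | None = None
    P_M: float | None = None
    g_of_S: object | None = None
    f_of_S: object | None = None

    def __post_init__(self):
        if self.form not in ("quadratic", "go_or_grow_linear", "logistic_uniform", "env_quadratic", "pressure_linear"):
            raise ConfigurationError(f"unknown fitness form {self.form!r}")
        if self.kappa <= 0:
            raise ConfigurationError("kappa must be positive")

    @property
    def saturation_scale(self) -> float:
        """Carrying-capacity scale 1/kappa (rho_M or P_M for go-or-grow forms)."""
        if self.rho_M is not None:
            return self.rho_M
        if self.P_M is not None:
            return self.P_M
        return 1.0 / self.kappa


def fitness_eval(spec: FitnessSpec, y, rho=0.0, S=None, P=None):
    """Evaluate the fitness R(y, rho, S or P)."""
    y = np.asarray(y, float)
    rho = np.asarray(rho, float)
    if spec.form == "quadratic":
        return spec.gamma - (y - spec.phi) ** 2 - spec.kappa * rho
    if spec.form == "go_or_grow_linear":
        r = as_profile(spec.r_of_y)
        return r(y) - spec.kappa * rho
    if spec.form == "logistic_uniform":
        k = spec.rho_M if spec.rho_M is not None else 1.0 / spec.kappa
        out = spec.gamma * (1.0 - rho / k)
        return out if y.ndim == 0 else np.broadcast_to(out, np.broadcast_shapes(y.shape, out.shape)).copy()
    if spec.form == "env_quadratic":
        if S is None:
            raise ConfigurationError("env_quadratic fitness requires a signal S")
        g = as_profile(spec.g_of_S)
        f = as_profile(spec.f_of_S)
        S = np.asarray(S, float)
        return g(S) - (y - f(S)) ** 2 - spec.kappa * rho
    if spec.form == "pressure_linear":
        if P is None:
            raise ConfigurationError("pressure_linear fitness requires the pressure P")
        r = as_profile(spec.r_of_y)
        return r(y) - spec.kappa * np.asarray(P, float)
    raise ConfigurationError(f"unknown fitness form {spec.form!r}")


@dataclass(frozen=True)
class PressureLaw:
    """Barotropic law P = Pi(rho): linear K*rho or power K*rho**gamma_exp."""

    form: str = "linear"
    K: float = 1.0
    gamma_exp: float = 2.0

    def __post_init__(self):
        if self.form not in ("linear", "power"):
            raise ConfigurationError(f"unknown pressure law {self.form!r}")
        if self.K <= 0:
            raise ConfigurationError("pressure scale K must be positive")
        if self.form == "power" and self.gamma_exp <= 1:
            raise ConfigurationError("power-law stiffness exponent must exceed 1")


def pressure_eval(law: PressureLaw, rho):
    rho = np.asarray(rho, float)
    if law.form == "linear":
        return law.K * rho
    return law.K * rho**law.gamma_exp


def inverse_pressure(law: PressureLaw, P):
    P = np.asarray(P, float)
    if law.form == "linear":
        return P / law.K
    return (P / law.K) ** (1.0 / law.gamma_exp)


@dataclass(frozen=True)
class SignalSpec:
    """Environmental signal: a frozen spatial profile or reaction-diffusion.

    The dynamic mode evolves  dS/dt = D_S Lap S + production - uptake*rho*S
    - decay*S  with zero-flux ends; linear uptake by cells is the mechanism
    that lets signal consumption drive propagating taxis waves.
    """

    mode: str = "static_profile"
    Sigma_of_x: object | None = None
    D_S: float = 0.0
    production: float = 0.0
    uptake: float = 0.0
    decay: float = 0.0
    S_init: float = 1.0  # uniform initial level for the dynamic mode

    def __post_init__(self):
        if self.mode not in ("static_profile", "reaction_diffusion"):
            raise ConfigurationError(f"unknown signal mode {self.mode!r}")
        if self.mode == "static_profile" and self.Sigma_of_x is None:
            raise ConfigurationError("static_profile mode requires Sigma_of_x")


def signal_rhs(spec: SignalSpec, S: np.ndarray, rho: np.ndarray, dx: float) -> np.ndarray:
    """dS/dt for the reaction-diffusion signal; zero-flux via ghost reflection."""
    if spec.mode != "reaction_diffusion":
        raise ConfigurationError("signal_rhs applies only to the reaction_diffusion mode")
    S = np.asarray(S, float)
    lap = np.empty_like(S)
    lap[1:-1] = (S[:-2] - 2 * S[1:-1] + S[2:]) / dx**2
    # ghost reflection S_0 = S_1, S_{N+1} = S_N
    lap[0] = (S[1] - S[0]) / dx**2
    lap[-1] = (S[-2] - S[-1]) / dx**2
    return spec.D_S * lap + spec.production - spec.uptake * rho * S - spec.decay * S


@dataclass(frozen=True)
class PhenotypeTransitionSpec:
    """Phenotypic diffusion rate Dbar >= 0 and constant drift Abar."""

    Dbar: float = 0.0
    Abar: float = 0.0

    def __post_init__(self):
        if self.Dbar < 0:
            raise ConfigurationError("Dbar must be non-negative")


@dataclass(frozen=True)
class ModelSpec:
    """One complete phenotype-structured PDE instance (zero-flux boundaries)."""

    motility: MotilitySpec
    fitness: FitnessSpec
    transitions: PhenotypeTransitionSpec = field(default_factory=PhenotypeTransitionSpec)
    pressure: PressureLaw | None = None
    signal: SignalSpec | None = None
    reaction_scale: float = 1.0
    name: str = ""

    def __post_init__(self):
        if (self.motility.kind == "pressure") != (self.pressure is not None):
            raise ConfigurationError("pressure law must be present iff motility kind is 'pressure'")
        needs_signal = self.motility.kind == "taxis" or self.fitness.form == "env_quadratic"
        if needs_signal and self.signal is None:
            raise ConfigurationError("this model references a signal S but none is configured")


def _check_go_or_grow(r, mobility, Y: float) -> None:
    """Assert the proliferation-migration trade-off shape on [0, Y]."""
    yy = np.linspace(0.0, Y, 101)
    rv = np.asarray(as_profile(r)(yy), float)
    mv = np.asarray(as_profile(mobility)(yy), float)
    if not (abs(rv[0] - 1.0) < 1e-9 and abs(rv[-1]) < 1e-9):
        raise ConfigurationError("go-or-grow requires r(0)=1 and r(Y)=0")
    if not (np.all(np.diff(rv) <= 1e-12) and np.all(np.diff(mv) >= -1e-12) and mv[0] > 0):
        raise ConfigurationError("go-or-grow requires decreasing r and increasing positive mobility")


def preset(name: str, **overrides) -> ModelSpec:
    """Build a named preset ModelSpec; keyword overrides are preset-specific."""
    try:
        builder = PRESETS[name]
    except KeyError:
        raise ConfigurationError(f"unknown preset {name!r}; known: {sorted(PRESETS)}") from None
    return builder(**overrides)


def _fisher_kpp(epsilon: float | None = None, D: float = 1.0, r: float = 1.0, k: float = 1.0) -> ModelSpec:
    """Fisher-KPP logistic invasion; with epsilon, the sharp-front rescaling
    (t, x) -> (t/eps, x/eps), i.e. diffusivity eps^2*D/eps = eps*D and
    reaction rate r/eps on the original coordinates."""
    if epsilon is None:
        Dc, scale = D, 1.0
    else:
        Dc, scale = epsilon * D, 1.0 / epsilon
    return ModelSpec(
        motility=MotilitySpec(kind="diffusion", D_of_y=constant(Dc)),
        fitness=FitnessSpec(form="logistic_uniform", gamma=r, rho_M=k, kappa=r / k),
        transitions=PhenotypeTransitionSpec(Dbar=0.0),
        reaction_scale=scale,
        name="fisher_kpp",
    )


def _diffusion_tradeoff(Dbar: float = 1e-3) -> ModelSpec:
    """Motility/proliferation trade-off: D(y)=y, R = 10(1-y) - 10 rho on y in [0,1]."""
    return ModelSpec(
        motility=MotilitySpec(kind="diffusion", D_of_y=linear(1.0)),
        fitness=FitnessSpec(form="go_or_grow_linear", r_of_y=linear(-10.0, 10.0), kappa=10.0, rho_M=1.0),
        transitions=PhenotypeTransitionSpec(Dbar=Dbar),
        name="diffusion_tradeoff",
    )


def _cane_toad(Dbar: float = 1e-2, r: float = 1.0) -> ModelSpec:
    """Dispersal-evolution model: D(y)=y, logistic R(rho) = r (1 - rho)."""
    return ModelSpec(
        motility=MotilitySpec(kind="diffusion", D_of_y=linear(1.0)),
        fitness=FitnessSpec(form="logistic_uniform", gamma=r, rho_M=1.0, kappa=r),
        transitions=PhenotypeTransitionSpec(Dbar=Dbar),
        name="cane_toad",
    )


def _nonlocal_selection(Dbar: float = 0.1) -> ModelSpec:
    """Space-free selection-mutation model with single-peak quadratic fitness."""
    return ModelSpec(
        motility=MotilitySpec(kind="diffusion", D_of_y=constant(0.0)),
        fitness=FitnessSpec(form="quadratic", gamma=10.0, phi=1.0, kappa=0.1),
        transitions=PhenotypeTransitionSpec(Dbar=Dbar),
        name="nonlocal_selection",
    )


def _pressure_go_or_grow(epsilon: float = 0.01, P_M: float = 1.0, mu0: float = 0.1,
                         stiffness: float = 3.0) -> ModelSpec:
    """Go-or-grow pressure model in the sharp-front/small-mutation rescaling:
    dn/dt = d/dx[mu(y) n dP/dx] + eps d2n/dy2 + n (r(y) - P/P_M)/eps,
    with r(y) = 1 - y and mu(y) = mu0 + (1 - mu0) y on y in [0, 1].

    The default barotropic law is the porous-medium form P = rho^3: a stiff
    law keeps the rear density plateau close to its limiting value rho_M at
    finite eps (the mutation-selection layer shifts the rear pressure by
    O(eps^(2/3)), and a stiffness gamma divides its effect on the density).
    Set stiffness=1 for the linear law."""
    r = linear(-1.0, 1.0)
    mu = linear(1.0 - mu0, mu0)
    _check_go_or_grow(r, mu, 1.0)
    law = PressureLaw(form="linear", K=1.0) if stiffness == 1 else PressureLaw(
        form="power", K=1.0, gamma_exp=stiffness)
    return ModelSpec(
        motility=MotilitySpec(kind="pressure", mu_of_y=mu),
        fitness=FitnessSpec(form="pressure_linear", r_of_y=r, kappa=1.0 / P_M, P_M=P_M),
        transitions=PhenotypeTransitionSpec(Dbar=epsilon),
        pressure=law,
        reaction_scale=1.0 / epsilon,
        name="pressure_go_or_grow",
    )


def _taxis_tradeoff(epsilon: float = 0.01, rho_M: float = 1.0, chi0: float = 0.1, D: float = 1.0, uptake: float = 1.0) -> ModelSpec:
    """Qualitative chemotaxis-proliferation trade-off (not a reproduction of
    any published parameterisation): consumed attractant drives the wave.

    Rescaled form: dn/dt = -d/dx[chi(y) n dS/dx] + eps D d2n/dx2
    + eps d2n/dy2 + n (r(y) - rho/rho_M)/eps, with S consumed by cells."""
    r = linear(-1.0, 1.0)
    chi = linear(1.0 - chi0, chi0)
    _check_go_or_grow(r, chi, 1.0)
    return ModelSpec(
        motility=MotilitySpec(kind="taxis", chi_of_y=chi, D_const=epsilon * D),
        fitness=FitnessSpec(form="go_or_grow_linear", r_of_y=r, kappa=1.0 / rho_M, rho_M=rho_M),
        transitions=PhenotypeTransitionSpec(Dbar=epsilon),
        signal=SignalSpec(mode="reaction_diffusion", D_S=epsilon * D, uptake=uptake / epsilon, S_init=1.0),
        reaction_scale=1.0 / epsilon,
        name="taxis_tradeoff",
    )


PRESETS = {
    "fisher_kpp": _fisher_kpp,
    "diffusion_tradeoff": _diffusion_tradeoff,
    "cane_toad": _cane_toad,
    "nonlocal_selection": _nonlocal_selection,
    "pressure_go_or_grow": _pressure_go_or_grow,
    "taxis_tradeoff": _taxis_tradeoff,
}
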