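"""Branching random walk: step rules, scaling map, determinism and the
diffusive-limit match to the continuum solver."""

import numpy as np
import pytest

from pspde.abm import (
    ABMConfig,
    ABMState,
    ScalingMap,
    abm_simulate,
    abm_step,
    ensemble_mean_density,
    probabilities_from_target,
)
from pspde.grids import ConfigurationError, make_grid
from pspde.models import (
    FitnessSpec,
    ModelSpec,
    MotilitySpec,
    PhenotypeTransitionSpec,
    SignalSpec,
)
from pspde.profiles import constant, linear


def lattice(nx=20, ny=5, Lx=2.0):
    return make_grid(0.0, Lx, nx, 0.0, 0.5, ny)


def uniform_occupancy(grid, n_per_site):
    return np.full(grid.shape, n_per_site, dtype=np.int64)


class TestScalingMap:
    def test_alpha_factors(self):
        sc = ScalingMap(hx=0.1, hy=0.2, tau=0.005)
        assert sc.alpha_x == pytest.approx(1.0)
        assert sc.alpha_y == pytest.approx(4.0)


class TestStepRules:
    def test_all_probabilities_zero_is_identity(self):
        grid = lattice()
        cfg = ABMConfig(grid=grid, tau=0.01, seed=3)
        state = ABMState(N=uniform_occupancy(grid, 4), k=0,
                         rng=np.random.default_rng(3), config=cfg)
        out = abm_step(state)
        np.testing.assert_array_equal(out.N, state.N)
        assert out.k == 1

    def test_pure_death_expectation(self):
        # expected total after k steps is N0 (1 - tau d)^k
        grid = lattice(nx=4, ny=1)
        d, tau, k_steps, n_rep = 5.0, 0.02, 10, 200
        totals = []
        ss = np.random.SeedSequence(99)
        for child in ss.spawn(n_rep):
            cfg = ABMConfig(grid=grid, tau=tau,
                            rD=lambda t, x, y, rho: np.full((4, 1), d), seed=None)
            state = ABMState(N=uniform_occupancy(grid, 100), k=0,
                             rng=np.random.default_rng(child), config=cfg)
            for _ in range(k_steps):
                state = abm_step(state)
            totals.append(state.total)
        expected = 400 * (1 - tau * d) ** k_steps
        se = np.std(totals, ddof=1) / np.sqrt(n_rep)
        assert abs(np.mean(totals) - expected) < 3 * se + 1e-9

    def test_symmetric_walk_displacement_variance(self):
        # per-cell displacement variance after k steps = k hx^2 / 2
        grid = make_grid(0.0, 20.0, 200, 0.0, 1.0, 1)
        k_steps, n_rep = 20, 150
        hx = grid.dx
        var_est = []
        ss = np.random.SeedSequence(7)
        start = 100  # central site index
        for child in ss.spawn(n_rep):
            cfg = ABMConfig(grid=grid, tau=0.01,
                            PLx=lambda t, x, y, rho: np.full(grid.shape, 0.25),
                            PRx=lambda t, x, y, rho: np.full(grid.shape, 0.25))
            N0 = np.zeros(grid.shape, dtype=np.int64)
            N0[start, 0] = 50
            state = ABMState(N=N0, k=0, rng=np.random.default_rng(child), config=cfg)
            for _ in range(k_steps):
                state = abm_step(state)
            pos = np.repeat(grid.x_centers, state.N[:, 0])
            var_est.append(np.mean((pos - grid.x_centers[start]) ** 2))
        expected = k_steps * hx**2 / 2.0
        se = np.std(var_est, ddof=1) / np.sqrt(n_rep)
        assert abs(np.mean(var_est) - expected) < 3 * se

    def test_conservation_without_birth_death(self, rng):
        grid = lattice()
        cfg = ABMConfig(grid=grid, tau=0.01, pLy=0.2, pRy=0.2,
                        PLx=lambda t, x, y, rho: np.full(grid.shape, 0.3),
                        PRx=lambda t, x, y, rho: np.full(grid.shape, 0.3))
        state = ABMState(N=uniform_occupancy(grid, 7), k=0, rng=rng, config=cfg)
        for _ in range(25):
            state = abm_step(state)
        assert state.total == 7 * grid.nx * grid.ny

    def test_invalid_probabilities_flagged_with_site(self):
        grid = lattice(nx=3, ny=1)
        cfg = ABMConfig(grid=grid, tau=0.5,
                        rP=lambda t, x, y, rho: np.full((3, 1), 3.0))  # tau rP = 1.5
        state = ABMState(N=uniform_occupancy(grid, 1), k=0,
                         rng=np.random.default_rng(0), config=cfg)
        with pytest.raises(ConfigurationError, match="site"):
            abm_step(state)


class TestSimulate:
    def test_determinism_identical_seeds(self):
        grid = lattice()
        cfg = ABMConfig(grid=grid, tau=0.01, pLy=0.1, pRy=0.1,
                        PLx=lambda t, x, y, rho: np.full(grid.shape, 0.25),
                        PRx=lambda t, x, y, rho: np.full(grid.shape, 0.25),
                        rP=lambda t, x, y, rho: np.full(grid.shape, 2.0))
        N0 = uniform_occupancy(grid, 5)
        _, fa, _ = abm_simulate(cfg, 0.1, initial=N0, seed=11)
        _, fb, _ = abm_simulate(cfg, 0.1, initial=N0, seed=11)
        np.testing.assert_array_equal(fa[-1].values, fb[-1].values)

    def test_seed_required(self):
        grid = lattice()
        cfg = ABMConfig(grid=grid, tau=0.01)
        with pytest.raises(ConfigurationError, match="seed"):
            abm_simulate(cfg, 0.1, initial=uniform_occupancy(grid, 1))

    def test_density_normalisation(self):
        grid = lattice()
        cfg = ABMConfig(grid=grid, tau=0.01, seed=5)
        _, fields, _ = abm_simulate(cfg, 0.02, initial=uniform_occupancy(grid, 8), seed=5)
        # n = N/(hx hy); rho = hy * sum_j n
        expected_n = 8.0 / (grid.dx * grid.dy)
        np.testing.assert_allclose(fields[-1].values, expected_n)


class TestProbabilitiesFromTarget:
    def test_symmetric_split_for_diffusion(self):
        grid = make_grid(0, 1, 10, 0, 0.4, 4)
        hx = hy = 0.1
        tau = hx**2 / 2  # alpha_x = 1
        model = ModelSpec(
            motility=MotilitySpec(kind="diffusion", D_of_y=constant(0.5)),
            fitness=FitnessSpec(form="logistic_uniform", gamma=0.0, rho_M=1.0, kappa=1e-12),
            transitions=PhenotypeTransitionSpec(Dbar=0.0),
        )
        cfg = probabilities_from_target(model, hx, hy, tau, grid=grid)
        PL = cfg.PLx(0.0, None, None, np.zeros(10))
        PR = cfg.PRx(0.0, None, None, np.zeros(10))
        np.testing.assert_allclose(PL, 0.25)
        np.testing.assert_allclose(PR, 0.25)

    def test_phenotype_switch_probabilities(self):
        grid = make_grid(0, 1, 4, 0, 1, 10)
        hx, hy = grid.dx, grid.dy  # 0.25, 0.1
        tau = hy**2 / 2  # alpha_y = 1
        model = ModelSpec(
            motility=MotilitySpec(kind="diffusion", D_of_y=constant(0.1)),
            fitness=FitnessSpec(form="logistic_uniform", gamma=0.0, rho_M=1.0, kappa=1e-12),
            transitions=PhenotypeTransitionSpec(Dbar=0.2),
        )
        cfg = probabilities_from_target(model, hx, hy, tau, grid=grid)
        assert cfg.pLy == pytest.approx(0.1)
        assert cfg.pRy == pytest.approx(0.1)

    def test_taxis_drift_sign(self):
        # dS/dx > 0 must bias movement rightwards (PR > PL)
        grid = make_grid(0, 1, 10, 0, 1, 2)
        hx, hy = grid.dx, grid.dy
        tau = hx**2 / 2
        model = ModelSpec(
            motility=MotilitySpec(kind="taxis", chi_of_y=constant(0.5), D_const=0.5),
            fitness=FitnessSpec(form="go_or_grow_linear", r_of_y=constant(0.0), kappa=1e-12),
            signal=SignalSpec(mode="static_profile", Sigma_of_x=linear(1.0)),
        )
        cfg = probabilities_from_target(model, hx, hy, tau, grid=grid)
        PL = cfg.PLx(0.0, None, None, np.zeros(10))
        PR = cfg.PRx(0.0, None, None, np.zeros(10))
        assert np.all(PR > PL)

    def test_unresolvable_probabilities_raise(self):
        grid = make_grid(0, 1, 4, 0, 1, 2)
        model = ModelSpec(
            motility=MotilitySpec(kind="diffusion", D_of_y=constant(5.0)),
            fitness=FitnessSpec(form="logistic_uniform", gamma=0.0, rho_M=1.0, kappa=1e-12),
            transitions=PhenotypeTransitionSpec(Dbar=0.0),
        )
        with pytest.raises(ConfigurationError):
            probabilities_from_target(model, grid.dx, grid.dy, grid.dx**2 / 2, grid=grid)


class TestUniformEnsembleMean:
    def test_symmetric_dynamics_preserve_uniform_mean(self):
        grid = lattice(nx=10, ny=4)
        cfg = ABMConfig(grid=grid, tau=0.01, pLy=0.25, pRy=0.25,
                        PLx=lambda t, x, y, rho: np.full(grid.shape, 0.25),
                        PRx=lambda t, x, y, rho: np.full(grid.shape, 0.25))
        N0 = uniform_occupancy(grid, 25)
        times, mean_rho = ensemble_mean_density(cfg, 0.1, N0, n_seeds=80, base_seed=2,
                                                record_times=[0.1])
        rho0 = 25.0 * grid.ny / grid.dx / (grid.ny / grid.dy)  # uniform density
        # interior sites stay at the uniform value within sampling error
        interior = mean_rho[-1][2:-2]
        assert np.abs(interior / interior.mean() - 1.0).max() < 0.05
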