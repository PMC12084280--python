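"""Deterministic synthetic fields and profiles for experiments and tests.

Every fixture has a documented closed form: sharp step fronts, (weighted)
Gaussian phenotype profiles, spatially-decaying initial seeds, and exactly
translating front series for validating the wave diagnostics.
"""

from __future__ import annotations

import numpy as np

from .grids import GridSpec, PhenotypeDensityField

__all__ = ["make_fixture", "step_profile", "gaussian_profile", "spatial_gaussian_field",
           "exponential_seed_field", "translating_front_series"]


def step_profile(x: np.ndarray, x0: float = 0.0, high: float = 1.0, low: float = 0.0) -> np.ndarray:
    """Sharp front: ``high`` for x < x0, ``low`` for x >= x0."""
    return np.where(np.asarray(x, float) < x0, high, low)


def gaussian_profile(y: np.ndarray, weight: float, mean: float, variance: float) -> np.ndarray:
    """Normalised Gaussian of integral ``weight``."""
    y = np.asarray(y, float)
    return weight / np.sqrt(2 * np.pi * variance) * np.exp(-((y - mean) ** 2) / (2 * variance))


def spatial_gaussian_field(grid: GridSpec, rho0, ybar0, var0) -> PhenotypeDensityField:
    """n(0, x, y) Gaussian in y at each x with weight rho0(x), mean ybar0(x),
    variance var0(x); scalars are broadcast."""
    x = grid.x_centers
    rho = np.broadcast_to(np.asarray(rho0(x) if callable(rho0) else rho0, float), x.shape)
    yb = np.broadcast_to(np.asarray(ybar0(x) if callable(ybar0) else ybar0, float), x.shape)
    vr = np.broadcast_to(np.asarray(var0(x) if callable(var0) else var0, float), x.shape)
    y = grid.y_centers[None, :]
    vals = rho[:, None] / np.sqrt(2 * np.pi * vr[:, None]) * np.exp(
        -((y - yb[:, None]) ** 2) / (2 * vr[:, None])
    )
    return PhenotypeDensityField(grid, vals)


def exponential_seed_field(grid: GridSpec, amplitude: float = 0.1, rate: float = 100.0) -> PhenotypeDensityField:
    """Invasion seed n(0, x, y) = amplitude * exp(-rate * x), uniform in y."""
    vals = amplitude * np.exp(-rate * grid.x_centers)[:, None] * np.ones((1, grid.ny))
    return PhenotypeDensityField(grid, vals)


def step_field(grid: GridSpec, x0: float = 0.0, high: float = 1.0) -> PhenotypeDensityField:
    """Step front in x, uniform in y, scaled so the density rho equals
    ``high`` on the occupied side."""
    prof = step_profile(grid.x_centers, x0, high, 0.0)
    y_extent = grid.dy * grid.ny
    vals = (prof / y_extent)[:, None] * np.ones((1, grid.ny))
    return PhenotypeDensityField(grid, vals)


def translating_front_series(x: np.ndarray, times: np.ndarray, speed: float,
                             steepness: float = 2.0, height: float = 1.0) -> np.ndarray:
    """Exactly translating logistic front rho(t, x) = h / (1 + exp(s (x - c t)))."""
    x = np.asarray(x, float)[None, :]
    t = np.asarray(times, float)[:, None]
    return height / (1.0 + np.exp(steepness * (x - speed * t)))


def make_fixture(kind: str, grid: GridSpec | None = None, **params):
    """Dispatch on fixture kind; see the individual constructors."""
    kinds = {
        "step": lambda: step_field(grid, **params),
        "gaussian": lambda: spatial_gaussian_field(
            grid, params.get("weight", 1.0), params.get("mean", 0.0), params.get("variance", 1.0)
        ),
        "exponential_seed": lambda: exponential_seed_field(grid, **params),
        "translating_front": lambda: translating_front_series(**params),
    }
    try:
        return kinds[kind]()
    except KeyError:
        raise ValueError(f"unknown fixture kind {kind!r}; known: {sorted(kinds)}") from None
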