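"""Grids, discrete phenotype-density fields and macroscopic reducers.

The state variable throughout the package is the cell phenotype density
``n(t, x, y)`` — cells per unit space per unit phenotype — stored as the
cell-averaged value on a uniform rectangular grid over physical space ``x``
and phenotypic state ``y``.  All integrals over phenotype are midpoint
(middle Riemann) sums, so the spatial cell density is

    rho_i = dy * sum_j n_{i,j}.

Cell centres follow the half-offset convention ``x_i = x_min + (i - 1/2) dx``
with 1-based cell index ``i``; ``Ny = 1`` is a legal degenerate grid for
phenotype-free (plain reaction-diffusion) models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GridSpec",
    "PhenotypeDensityField",
    "MacroscopicState",
    "make_grid",
    "density",
    "prevailing_phenotype",
    "phenotype_moments",
    "macroscopic_state",
]


class ConfigurationError(ValueError):
    """Invalid model or grid configuration."""


@dataclass(frozen=True)
class GridSpec:
    """Uniform cell-centred grid over physical space and phenotype space.

    Attributes
    ----------
    x_min, x_max : float
        Extent of the physical domain (arbitrary length units).
    y_min, y_max : float
        Extent of the phenotype domain (dimensionless trait coordinate).
    nx, ny : int
        Number of grid cells along each axis.
    """

    x_min: float
    x_max: float
    nx: int
    y_min: float
    y_max: float
    ny: int

    @property
    def dx(self) -> float:
        return (self.x_max - self.x_min) / self.nx

    @property
    def dy(self) -> float:
        if self.ny == 1 and self.y_max == self.y_min:
            # degenerate phenotype axis: unit weight so rho == n
            return 1.0
        return (self.y_max - self.y_min) / self.ny

    @property
    def x_centers(self) -> np.ndarray:
        return self.x_min + (np.arange(1, self.nx + 1) - 0.5) * self.dx

    @property
    def y_centers(self) -> np.ndarray:
        if self.ny == 1 and self.y_max == self.y_min:
            return np.array([self.y_min])
        return self.y_min + (np.arange(1, self.ny + 1) - 0.5) * self.dy

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nx, self.ny)


def make_grid(
    x_min: float,
    x_max: float,
    nx: int,
    y_min: float = 0.0,
    y_max: float = 0.0,
    ny: int = 1,
) -> GridSpec:
    """Build a uniform cell-centred grid.

    ``y_max == y_min`` is accepted only for the degenerate case ``ny == 1``
    (no phenotype structure); then the phenotype weight ``dy`` is 1 so that
    densities and phenotype densities coincide.
    """
    if nx < 1 or ny < 1:
        raise ConfigurationError(f"cell counts must be >= 1, got nx={nx}, ny={ny}")
    if not x_max > x_min:
        raise ConfigurationError(f"need x_max > x_min, got [{x_min}, {x_max}]")
    if y_max < y_min or (y_max == y_min and ny != 1):
        raise ConfigurationError(f"need y_max > y_min (or equal with ny=1), got [{y_min}, {y_max}], ny={ny}")
    return GridSpec(float(x_min), float(x_max), int(nx), float(y_min), float(y_max), int(ny))


@dataclass
class PhenotypeDensityField:
    """Cell-averaged phenotype density ``n`` on a :class:`GridSpec`.

    ``values`` has shape ``(nx, ny)`` and must be finite and non-negative up
    to a small configured slack (round-off from conservative schemes).
    """

    grid: GridSpec
    values: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ConfigurationError(
                f"field shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    def validate(self, tol: float | None = None) -> None:
        """Raise if the field contains non-finite entries or negatives beyond tol."""
        if not np.all(np.isfinite(self.values)):
            raise FloatingPointError(f"non-finite density at t={self.time}")
        if tol is None:
            tol = 1e-12 * max(self.values.max(initial=0.0), 1.0)
        if self.values.min(initial=0.0) < -tol:
            raise FloatingPointError(
                f"negative density {self.values.min():.3e} beyond tolerance {tol:.3e} at t={self.time}"
            )

    def copy(self) -> "PhenotypeDensityField":
        return PhenotypeDensityField(self.grid, self.values.copy(), self.time)

    @property
    def mass(self) -> float:
        """Total cell number, dx*dy*sum(n)."""
        return float(self.grid.dx * self.grid.dy * self.values.sum())


@dataclass
class MacroscopicState:
    """Per-column macroscopic reductions of a phenotype density field.

    ``ybar``, ``mean_y`` and ``var_y`` are masked where the column carries no
    mass (the prevailing phenotype of an empty column is undefined).
    """

    rho: np.ndarray
    ybar: np.ma.MaskedArray
    mean_y: np.ma.MaskedArray
    var_y: np.ma.MaskedArray
    S: np.ndarray | None = None
    P: np.ndarray | None = None


def density(fld: PhenotypeDensityField) -> np.ndarray:
    """Spatial cell density rho_i = dy * sum_j n_{i,j} (midpoint sum)."""
    return fld.grid.dy * fld.values.sum(axis=1)


def prevailing_phenotype(fld: PhenotypeDensityField) -> np.ma.MaskedArray:
    """Locally prevailing phenotype: the y-centre maximising n per column.

    Ties break to the lowest phenotype index (argmax convention).  Columns
    with zero mass are masked (undefined).
    """
    idx = np.argmax(fld.values, axis=1)
    ybar = fld.grid.y_centers[idx]
    empty = fld.values.sum(axis=1) <= 0.0
    return np.ma.MaskedArray(ybar, mask=empty)


def phenotype_moments(
    fld: PhenotypeDensityField,
) -> tuple[np.ndarray, np.ma.MaskedArray, np.ma.MaskedArray]:
    """Midpoint-quadrature weight, mean and variance of y per spatial column.

    Returns ``(rho, mean_y, var_y)``; mean and variance are masked where
    ``rho == 0``.  The variance is the second central moment of the discrete
    distribution on cell centres.
    """
    dy = fld.grid.dy
    y = fld.grid.y_centers
    rho = dy * fld.values.sum(axis=1)
    empty = rho <= 0.0
    safe = np.where(empty, 1.0, rho)
    mean = dy * (fld.values * y).sum(axis=1) / safe
    var = dy * (fld.values * (y[None, :] - mean[:, None]) ** 2).sum(axis=1) / safe
    return (
        rho,
        np.ma.MaskedArray(mean, mask=empty),
        np.ma.MaskedArray(np.maximum(var, 0.0), mask=empty),
    )


def macroscopic_state(
    fld: PhenotypeDensityField,
    S: np.ndarray | None = None,
    P: np.ndarray | None = None,
) -> MacroscopicState:
    rho, mean, var = phenotype_moments(fld)
    return MacroscopicState(
        rho=rho,
        ybar=prevailing_phenotype(fld),
        mean_y=mean,
        var_y=var,
        S=S,
        P=P,
    )
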