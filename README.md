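# pspde

Simulation and analysis toolkit for **phenotype-structured partial
differential equations (PS-PDEs)** — continuum models of collective cell
migration in which the population density `n(t, x, y)` is structured over
physical position `x` *and* a continuous phenotypic trait `y` (e.g. a
motility/proliferation trade-off axis). It is aimed at mathematical
biologists studying travelling invasion waves, evolutionary concentration
phenomena, and the structuring of phenotypes across moving fronts.

## What it solves

The unified 1+1-dimensional model

```
∂t n = ∂x[ D(y) ∂x n − A n ] + D̄ ∂²yy n + n R(y, ρ, S, P),
ρ(t,x) = ∫ n(t,x,y) dy
```

with movement mechanisms

- **diffusion**: trait-dependent diffusivity `D(y)` (Fisher-KPP and
  cane-toad–type dispersal models),
- **pressure**: advection down gradients of a barotropic pressure
  `P = Π(ρ)` with trait-dependent mobility `μ(y)`,
- **taxis**: advection up gradients of a signal `S(t,x)` with
  trait-dependent sensitivity `χ(y)` (Keller-Segel–type),

discretised by a finite-volume method of lines (central diffusive fluxes,
first-order upwind advection, midpoint Riemann sums for the non-local
density, zero-flux boundaries) with explicit, backward-Euler or IMEX time
stepping.

Alongside the PDE solver the package provides:

- `pspde.nonlocal_evolution` — the space-free selection–mutation model,
  its **exact Gaussian moment ODEs** (the analytical oracle for weight,
  mean trait and variance), the WKB/Hopf–Cole transform `u = ε log n`, and
  concentration diagnostics for the small-mutation scaling limit.
- `pspde.age_structured` — the McKendrick–von Foerster renewal model with
  characteristic-aligned stepping (pure ageing is exact).
- `pspde.abm` — the on-lattice branching random walk whose diffusive limit
  is the PS-PDE, with utilities that invert the limit relations so lattice
  probabilities match a given continuum model.
- `pspde.waves` — level-set wave-speed estimation, wave-frame resampling,
  and residuals of the go-or-grow structuring relation `ρ(z) = ρ_M r(ȳ(z))`.
- `pspde.experiments` + a `pspde` CLI — reproducible presets with HDF5/CSV/
  JSON outputs.

## Worked example

Sharp-front logistic invasion (`ε ∂t ρ = ε² ∂²xx ρ + ρ(1 − ρ)` with
`ε = 0.1`), whose fronts approach the minimal wave speed `c* = 2`:

```python
from pspde.experiments import fisher_wave_run

out = fisher_wave_run(epsilon=0.1)
est = out["wave"]
print(f"pooled speed {est.speed:.3f}, level spread {est.spread:.4f}")
```

prints

```
pooled speed 1.986, level spread 0.0001
```

i.e. the 0.2/0.5/0.8 level sets all advance at 1.986 length units per unit
time (within 0.7% of the analytic minimal speed; the residual is the
documented first-order discretisation bias), and their slopes agree to
0.01%, the operational signature of a travelling wave of fixed shape.

Selection of the fittest trait in the rescaled selection–mutation model
(quadratic fitness peaked at `φ = 1`, `ε = 0.1`):

```python
from pspde.experiments import concentration_run

out = concentration_run(epsilon=0.1)
tr = out["trajectory"]
print(f"mean trait {tr.mean_y[-1]:.3f}, population size {tr.rho[-1]:.1f}")
```

```
mean trait 0.995, population size 99.0
```

The mean trait has relaxed to the fitness peak (the exact trajectory is
`1 − 2e^{−2t}`, so 0.995 at `t = 3`) and the population size sits at the
finite-ε equilibrium `(γ − ε)/κ = 99.0`.

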