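# Methods

## Models

The central object is the phenotype density `n(t, x, y)` (cells per unit
space per unit trait) on a one-dimensional physical domain and a
one-dimensional trait interval, evolving under

```
∂t n = ∂x[ D(y) ∂x n − A n ] + D̄ ∂²yy n − Ā ∂y n + s · n R(y, ρ, S, P)
```

with `ρ = ∫ n dy` and zero-flux boundaries in both variables. The
interface velocity `A` selects the movement mechanism: `A = 0` (pure trait
-dependent diffusion), `A = −μ(y) ∂x P` with a barotropic law `P = Π(ρ)`
(pressure-driven dispersal), or `A = χ(y) ∂x S` (taxis along a signal).
`D̄` is the rate of undirected phenotypic change (mutation/stochastic
switching), `Ā` an optional directed trait drift. The fitness `R` is the
net per-capita growth rate; the shipped forms are logistic in `ρ`,
linear trade-off `r(y) − κρ` (or `− κP`), quadratic single-peak
`γ − (y − φ)² − κρ`, and its environment-dependent variant
`g(S) − (y − f(S))² − κρ`.

The factor `s = reaction_scale` carries the `1/ε` of the two asymptotic
scalings used throughout:

- **sharp-front scaling** `(t, x) → (t/ε, x/ε)`: diffusivity `εD`,
  reaction `R/ε` — fronts become step-like and move at the minimal wave
  speed;
- **small-mutation scaling** `D̄ = ε²` plus `t → t/ε` (effective trait
  diffusivity `ε`, reaction `R/ε`), with initial trait variance `σ₀² = ε` —
  the trait distribution concentrates toward a moving Dirac mass whose
  location obeys the canonical equation `dȳ/dt = 2(φ − ȳ)` and whose
  weight is pinned by `R(ȳ, ρ) = 0`.

Keeping the model coefficients O(1) and isolating `1/ε` in
`reaction_scale` makes the rescalings an exact change of variables at the
discrete level (asserted to round-off in the tests).

## Discretisation

Uniform cell-centred grids (`x_i = x_min + (i − 1/2)Δx`, 1-based);
integrals are midpoint sums, so the density reduction is
`ρ_i = Δy Σ_j n_{ij}`. Spatial fluxes combine central differences for the
diffusive part with first-order upwinding for advection,

```
F_{i+1/2,j} = D(y_j)(n_{i+1,j} − n_{ij})/Δx − (A)₊ n_{ij} − (A)₋ n_{i+1,j},
```

boundary interface fluxes are zeroed (finite-volume zero-flux); the trait
operator is the three-point stencil with ghost reflection at the trait
boundaries plus upwinded drift when `Ā ≠ 0`. Both operators telescope, so
total mass is conserved exactly (to round-off) when `R = 0`.

Time stepping:

- **explicit Euler**, refusing any `Δt` above the stability bound
  `min(Δx²/2 max D, Δy²/2D̄, Δx/max|A|, Δy/|Ā|, 1/max|sR|)` rather than
  silently sub-stepping (configured experiments stay reproducible);
- **backward Euler**, solving the linear system (matrix-free LGMRES) with
  the non-local quantities (ρ, P, S) lagged at the previous Picard iterate
  — the integral coupling would otherwise densify the Jacobian;
- **IMEX**: transport and the positive reaction part explicit, the
  negative reaction part implicit pointwise
  (`n⁺ = (n + Δt(M + C + nR₊))/(1 − ΔtR₋)`), which preserves positivity
  whenever the explicit transport update does; the explicit transport part
  still enforces its own CFL bound.

Negative densities beyond `1e−12·max n` raise instead of being clipped —
clipping masks scheme bugs. A dynamic signal is integrated on the same
time grid by first-order operator splitting (signal step with the pre-step
density, then the density step).

### Resolving pulled fronts

The logistic invasion front is *pulled*: its speed is fixed by the
linearisation on the exponentially decaying leading edge (decay length `ε`
in the sharp-front scaling). The discrete scheme has its own linear
spreading speed

```
c(Δx, Δt) = min_λ  ln[1 + Δt(r + 2D(cosh λΔx − 1)/Δx²)] / (λ Δt),
```

spatial discreteness raises it, the explicit-Euler growth factor lowers
it. The defaults keep `Δx = ε/2` and `Δt·r ≤ 1/80`, for which the
dispersion relation puts the discrete speed within 0.3% of the analytic
`c* = 2`; coarser grids (e.g. `Δx = 2.5ε`) visibly miss the speed, which
is a property of under-resolving the front tail, not of the window used to
fit it.

A corollary for advection-only (pressure) models with `1/ε` growth: any
exponential tail — whether in the initial condition or injected by upwind
leakage — is amplified into an artificial pulled front of speed
`~ r/(ελ)`. The go-or-grow preset therefore seeds with compact support and
uses moderately fine grids; the residual foot of the computed wave is
documented below.

## Analytical oracles

- **Gaussian moment system.** For quadratic fitness and Gaussian initial
  data the space-free model has an exact Gaussian solution whose weight,
  mean and inverse variance `(ρ, ȳ, v)` solve three ODEs; these are
  integrated with an adaptive RK at tolerances `1e−10` and serve as ground
  truth for the PDE solver (matched within 1% in the tests). In the
  small-mutation scaling the variance is pinned at `ε` and the mean obeys
  the canonical equation *exactly for every ε* — so numerical deviations
  from `ȳ(t) = φ + (ȳ⁰ − φ)e^{−2t}` are pure discretisation error. That
  error scales like `Δy²/ε²` (verified by refinement), which is why the
  concentration runs resolve `Δy ∝ √ε` and the canonical-equation checks
  assert tight absolute tolerances per ε rather than a monotone-in-ε error
  (the continuum error is identically zero at all ε).
- **Concentration diagnostics.** Convergence to a Dirac mass is measured
  by three surrogates that all shrink with ε: the solution variance, the
  maximum of the WKB transform `u = ε log n`, and the residual of the
  weight relation `|R(ȳ, ρ)|` (which equals ε exactly at the finite-ε
  equilibrium of the quadratic model — a built-in scale for the check).
- **Characteristic-aligned ageing.** The age-structured solver steps with
  `Δa = Δt`, making pure transport exact; survival multiplies by
  `1 − Δt·μ(a)` (the compartment transition factor), and the renewal
  integral is a midpoint sum over the updated distribution. The
  generational-wave experiment uses `Δt = 0.025`, age cut-off 120 with a
  tail-mass audit.

## Agent-based model

A discrete-time branching random walk on the space×trait lattice: per step
each cell divides/dies/stays (probabilities `τ·rP`, `τ·rD`), then moves
(left/right/stay), then switches trait — daughters move and switch in the
same step like any cell. Off-lattice moves are aborted (zero-flux
analogue); `ρ` enters rates from the pre-step occupancy (synchronous
update). Under `h², τ → 0` with `h²/2τ → α` the ensemble mean follows the
PS-PDE; `probabilities_from_target` inverts the limit relations
(`PL + PR = D(y)/α_x`, `PL − PR` from the drift, `pL_y = pR_y = D̄/2α_y`)
and validates that all probabilities stay in `[0, 1]`. All runs require an
explicit seed; ensembles spawn child seeds deterministically via
`SeedSequence`, so identical seeds give bit-identical trajectories.

The ABM↔PDE comparison uses a trade-off population (`D(y) = y`,
`r(y) = 10(1 − y)`) with carrying capacity scale `1/κ = 500` so that ≥10⁴
agents represent an O(1)-density population (the continuum model is
invariant under jointly rescaling `n` and `1/κ`, so this is purely a
choice of units). Both lattices (`h = 0.2, 0.1`, `τ = h²/2`) are compared
against one fine fixed-grid continuum solve aggregated onto the lattice;
at 100 seeds the ensemble noise floor sits well below the O(h) bias, so
the refinement trend is measurable.

## Go-or-grow preset and the structuring relation

The pressure preset uses `r(y) = 1 − y`, `μ(y) = 0.1 + 0.9y` on `y ∈
[0, 1]` (decreasing proliferation, increasing mobility, `r(0) = 1`,
`r(Y) = 0`) and, by default, the stiff barotropic law `P = ρ³`. The
stiffness is a deliberate choice: at finite ε the rear of the wave carries
a mutation–selection boundary layer of width `~ ε^{2/3}` in trait, shifting
the rear pressure off `P_M` by that order; a law of stiffness `γ` divides
the effect on the density by `γ`, keeping the rear density within 2% of
`ρ_M` at `ε = 0.01` (a linear law would need `ε ≲ 0.003`, which is out of
reach at the resolutions used here).

Across the computed wave the prevailing trait rises monotonically from
`≈ 0` at the rear toward the motile end at the front, and the zero-fitness
relation `ρ(z) = Π⁻¹(P_M r(ȳ(z)))` holds to well under 5% of `ρ_M`
throughout the saturated bulk and the transition (`ρ ≥ 0.75 ρ_M`). In the
wave *foot* the relation degrades: there the concentration ansatz only
applies in the ε → 0 limit (`ȳ` must climb to `Y` exactly at the edge), and
the foot is additionally contaminated by upwind leakage amplified at rate
`1/ε`. The structuring diagnostics therefore report the foot but the
quantitative relation is asserted on the bulk.

## Experiment presets and problem sizes

| preset | grid | steps | wall time |
|---|---|---|---|
| `fisher_wave` (ε = 0.01) | 10 000 × 1 | 160 000 | ~45 s |
| `concentration` (ε = 0.01) | 1 × 2000 | adaptive RK | ~3 s |
| `age_waves` | 4 800 ages | 4 000 | < 1 s |
| `go_or_grow` (ε = 0.01) | 1 000 × 25 | 24 000 | ~15 s |
| `abm_vs_pde` (h = 0.1) | 100 × 10 lattice | 200 × 100 seeds | ~10 s |

These sizes were chosen so each quantity is converged at the tolerance its
check asserts (front speed: dispersion analysis above; moments: second-
order in Δy; ABM: noise floor below bias), while a full validation sweep
stays comfortable on a single core.

## What the synthetic experiments do and do not show

All experiments use synthetic initial data (steps, Gaussians, compact
seeds) and the parameter sets of the model families themselves; there is
no measured biological data anywhere. Passing checks therefore validate
the *mathematics* — scheme correctness, agreement with exact solutions and
limits — not the biological fidelity of any particular parametrisation.
Known limitations: 1+1 dimensions only; uniform meshes; first-order
upwinding (no flux limiters), so advection-dominated profiles carry O(Δx)
smearing; the taxis preset's signal equation (linear uptake reaction–
diffusion) is a modelling choice, configurable but not derived; the
implicit scheme lags non-local couplings, so it is first-order accurate in
their feedback; and the foot of go-or-grow waves at finite ε is resolution
-limited as described above.
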