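# Methods

## Model overview

`adhesim` simulates a self-adhesive cell population whose deterministic
motion is driven by pairwise adhesion forces and whose stochastic motion is
a velocity-jump process along tissue fibers. The package covers three
levels that are connected by formal upscaling:

1. an agent-based model (`micro`) of N cells with damped Newtonian dynamics
   and mean-field (1/N-scaled) pairwise adhesion, optionally extended by a
   bound-CAM fraction per cell evolving by mass-action binding kinetics;
2. the equilibrium closure of the fast CAM kinetics (`cam`), a non-linear
   integral equation for the bound-CAM density;
3. macroscopic integro-PDEs (`macro`) for the cell density, obtained in the
   parabolic limit (myopic diffusion + non-local adhesion) or the hyperbolic
   limit (conservative transport with first-order corrections).

All grid-based solving is one-dimensional; the pointwise kernel operations
(potential, gradient, adhesion quadrature, ring operator) are generic in the
dimension where noted.

## The adhesion kernel and its discretisation

The adhesion potential is `H_r(x) = (r|B_r|)^-1 ∫_{min(|x|,r)}^r F(s) ds`
with a non-negative force profile `F` on `[0, r]`. Its gradient is
discontinuous at the origin and on the sensing sphere; the package uses the
conventions `sign(0) = 0` (no force between coincident cells) and the
one-sided value `F(r)` on the sphere, matching the grid stencil below.
With the normalisation `1/(r|B_r|)` and `F(0) = d + 1`, the non-local
operator `A_r u = ∇H_r ⋆ u` converges to the local gradient `∇u` as
`r → 0` at rate O(r); the test suite verifies this limit.

Two evaluation paths exist deliberately:

* `adhesion_point` — adaptive quadrature (absolute tolerance 1e-10), the
  slow oracle;
* `adhesion_grid_1d` — the production path: a right-Riemann sum implemented
  as a discrete cross-correlation with the weight stencil
  `w_l = sign(l) F(|l h|)`, offsets `l = -(l_r - 1) .. l_r`,
  `l_r = round(r/h)`, density extended by zero outside `[0, L]`.

The right-Riemann index range is **one-sided**: the offset `+l_r` is
included, `-l_r` is not. Consequently the stencil is not antisymmetric — on
a constant field it leaves a residue `h·u·F(r)`, and mirror symmetry of a
symmetric initial state holds only up to this O(h) bias, which slowly
drifts aggregate positions over long runs. This is an intentional
reproduction of the reference scheme for the 1D study, not an oversight;
`stencil="left"` selects the mirror-image convention, and
reflection-conjugation (reflect the data, switch the stencil) is an exact
symmetry that the tests check to round-off. The one-sided stencil also
limits the overall scheme to first-order convergence: on the D0 = 3
aggregation run the relative L1 change of the final profile halves per
refinement (measured 8.4% for h 0.02→0.01 and 4.2% for 0.01→0.005).

## Macroscopic solver

The parabolic equation

```
(a+1) ∂t u = c1 ∂x(D(x) ∂x u) + ∂x( u (θ c1 D'(x) − χ A_r u) ),
c1 = 1/(2a+1) · d/(d+2)     (= 1/9 for a = d = 1)
```

is advanced by outer operator splitting: on each window of length
`dt_outer` the adhesion field (computed by the grid stencil from the
window-initial density and interpolated linearly between nodes) is frozen,
turning the window problem into a linear advection–diffusion equation. That
problem is integrated implicitly — trapezoidal steps on the fixed inner mesh
`dt_outer / inner_substeps` with banded tridiagonal solves. An explicit
inner integrator was rejected: at h = 0.01 the diffusion stability limit
would force steps orders of magnitude below the inner mesh.

Space is discretised by a conservative finite-volume stencil on nodes
`x_m = m h` including both endpoints; boundary nodes own half cells. Fluxes
live on faces: diffusion by central differences with the face-midpoint
diffusion coefficient, advection with centred density averaging by default
(`advection="upwind"` is available as a donor-cell switch for very steep
aggregates; the study runs do not need it — densities stay non-negative).
No-flux boundaries are imposed by zeroing the boundary face fluxes, so the
finite-volume (trapezoid-weight) mass is conserved to round-off at every
inner step. Mass accounting throughout the package uses these
finite-volume weights.

Defaults follow the 1D study conditions: domain (0, 6), final time 25,
h = dt_outer = 0.01, 41 inner substeps, a = 1, r = 1, F ≡ 1, uniform
initial density 5, D(x) = D0 + δx with E ≡ 0. The affine `D` is supplied
as a free coefficient field: in 1D a normalised fiber distribution would
force D[q] ≡ 1, so the solver treats `E[q]`/`D[q]` as independent model
inputs rather than deriving them from a `q`.

`θ` multiplies the drift `c1 D'(x)` produced by splitting the myopic
diffusion `∂x∂x(D u)` into divergence form; `θ = 0` yields ordinary Fickian
diffusion with the same coefficient, which preserves aggregate positions
less strongly.

### CAM coupling

In CAM mode the adhesion flux is `∂x(χ μ₁ A_r u)`: sensitivity proportional
to the bound-CAM density. Per outer window the solver (i) re-equilibrates
`μ₁` from the current density by the fixed-point solver below, (ii) freezes
the bound *fraction* `μ₁/u` as the adhesion prefactor, and (iii) advances
the window implicitly as before. Freezing the fraction (rather than `μ₁`
itself) makes the no-unbinding limit `K⁻ = 0` (where `μ₁ = u`) coincide
exactly with the plain parabolic solver. The chemical field S is static in
time, which keeps the binding kernel matrices fixed across a run; snapshots
of `μ₁` are re-equilibrated against the recorded density.

### Hyperbolic modes

`mode="cte"` solves `(a+1) ∂t u + d/(d+1) ∂x(E u) = 0` with explicit
donor-cell upwinding on the outer mesh and refuses to run if the CFL number
`|E| dt (d/(d+1)) / ((a+1) h)` exceeds one. `mode="hyperbolic"` adds the
O(ε) corrections — myopic diffusion, the cross term
`−ε d²/((a+1)²(d+1)²) ∂x(E ∂x(uE))`, and the adhesion flux — inside the
implicit splitting scheme (transport upwinded in the operator), and
collapses identically to the parabolic solver when E ≡ 0 and ε = 1.

## Bound-CAM equilibrium

The binding/unbinding rates `k±(S, ρ)` vanish for pair distances `ρ ≥ r`.
The field operators `𝒢±` integrate `k±(S((x+x')/2), |x−x'|)/|B_r|` against a
density over the band `|x−x'| < r` (Riemann sum on the grid, midpoint
chemical values by linear interpolation, zero extension outside the
domain). The equilibrium bound-CAM density solves

```
μ₁ = μ₀ · 𝒢⁺(μ₀−μ₁) / (𝒢⁺(μ₀−μ₁) + 𝒢⁻ μ₁)
```

by damped Picard iteration: `μ₁ ← (1−ω) μ₁ + ω μ₀ Y(μ₀, μ₁)` with ω = 0.5,
start `μ₀/2`, sup-norm residual tolerance 1e-10, at most 10⁴ sweeps, iterate
clipped to `[0, μ₀]`. Existence of the equilibrium requires a positive
denominator wherever cells are present; the solver raises a hard error
(naming the node) if that fails, rather than regularising silently. Nodes
without cells satisfy the equation trivially and are exempt. Uniqueness for
general non-local kernels is open; the solver reports non-convergence
instead of resolving multi-stability.

The example rate family `k± = K±(S)(r^b± − ρ^b±)^{±a±}` produces sharply
accelerating detachment as `ρ → r`; since the unbinding profile blows up
there while the theory requires essential boundedness, `k⁻` is clipped at a
configurable ceiling (default 1e6). In the local-kernel limit the fixed
point reduces to `μ₁ = √K⁺/(√K⁺+√K⁻) μ₀`, which is also exposed directly.

The mesoscopic reconstruction factorises the equilibrium kinetic density as
`μ₀ · q(v) · ξ₁(|v|)` with the speed profile
`ξ₁(v) = d/(da−1) (|v|^{−d+1/a} − 1)` (logarithmic in the resonant case
`a = 1/d`); the profile integrates to `μ₀` over the velocity ball for any
drag `a`.

## Particle model

Deterministic stepping is fixed-step RK4 (chosen over adaptive integrators
for bit-reproducibility; steps satisfy `a·dt ≤ 0.1` in all shipped
configurations). The simulator refuses to run when the speed-cap condition
`(r|B_r|)^-1 sup χ · sup F ≤ a` fails, since velocities could then leave
the unit ball; under the condition the bound `|v_i| ≤ 1` and the barrier
`y_i ∈ [0, 1]` are invariants, which the tests monitor along trajectories
(bound fractions are clipped against round-off at the barrier).

Pairwise forces are O(N²) with distance cutoff; for the constant force
profile in 1D an O(N log N) counting shortcut (neighbours to the right
within `r`, including the sphere, minus neighbours to the left) produces
the same sums to floating-point accuracy and is used automatically.
Turning is simulated by Poisson thinning with unit rate — turn probability
`1 − exp(−dt)` per step — with the new direction drawn from the fiber
distribution and the speed uniform on (0, 1); this uniform speed law is the
unique sampling density consistent with a direction-only turning kernel.
Each run records its seed and generator in the trajectory metadata.

## Synthetic inputs and what the tests show

All inputs are generated in code: uniform or Gaussian-bump initial
densities, affine diffusion fields, constant chemical fields, seeded
particle clouds, and the separable binding-rate family. These reproduce the
idealised study conditions — point cells, a single CAM species, constant
sensitivity, static chemistry, 1D geometry — and deliberately omit features
of real migrating tissue: volume exclusion, cell division and death,
heterogeneous subpopulations, mechanics of the extracellular matrix, and
genuinely 2D/3D geometry. Passing tests therefore validate the numerics
and internal consistency of this model family (micro ↔ macro agreement,
equilibrium closures, conservation), not biological fidelity.

Problem sizes in the shipped suite: full aggregation runs use the study
meshes (601 nodes, 2500 outer windows); refinement studies go to h = 0.005;
particle checks use N up to 5000 (deterministic) and 10⁵ (binning
statistics).

## Aggregate diagnostics

An aggregate is a maximal contiguous run of nodes with density strictly
above a threshold; its peak is the run's maximum node (leftmost on ties).
The default threshold equals the initial uniform level (5): aggregates are
tight against a depleted background, so any threshold strictly between
background and peak yields the same count, and the initial level is the
only parameter-free choice. The suite also reports how the count responds
across thresholds rather than assuming one. "Aggregate density" comparisons
use the maximum of the final profile.

## Known limitations

* The grid PDE solver is 1D; d ≥ 2 is supported only for pointwise kernel
  operations and the particle model's deterministic part.
* The one-sided adhesion stencil limits convergence to first order and
  introduces a slow rightward drift of aggregates (O(h)); use `stencil`
  to flip, or refine the mesh, if symmetry matters more than
  reproduction of the reference scheme.
* Centred advection can in principle undershoot for extremely steep
  aggregates; the donor-cell switch trades accuracy for positivity.
* The macroscopic CAM coupling assumes instantaneous equilibration of the
  binding kinetics and a time-static chemical field.
* The turning simulation is 1D and uses a unit turning rate.
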