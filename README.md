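# adhesim

Multiscale simulation of **non-local cell–cell adhesion** in migrating cell
populations — from agent-based dynamics with cell-adhesion-molecule (CAM)
binding kinetics up to macroscopic integro-PDEs with myopic diffusion.

Cell–cell adhesion organises tissues during embryogenesis and is reprogrammed
in cancer: loss of E-cadherin during the epithelial–mesenchymal transition
yields cells that migrate more freely yet retain enough adhesiveness to form
aggregates. `adhesim` is for modellers who want to simulate this interplay at
three coupled levels of description and check that they agree:

* **micro** — N point cells with positions `x_i`, velocities `v_i` in the unit
  ball, and optionally bound-CAM fractions `y_i ∈ [0,1]`, following

  dx_i/dt = v_i,
  dv_i/dt = −a v_i + χ(t,x_i) [y_i] (1/N) Σ_{j≠i} ∇H_r(x_i − x_j),
  dy_i/dt = (1/N) Σ_{j≠i} [G⁺(1−y_i)(1−y_j) − G⁻ y_i y_j],

  with Stokes drag `a`, adhesion sensitivity `χ`, and the adhesion potential
  `H_r(x) = (r|B_r|)⁻¹ ∫_{min(|x|,r)}^r F(s) ds` supported on the sensing ball
  of radius `r`. Stochastic re-orientation along tissue fibers is realised as
  a velocity-jump process (unit-rate turning, new direction from the fiber
  distribution `q`, speed uniform on (0,1)).
* **cam** — the macroscopic equilibrium of fast CAM binding: the bound-CAM
  density `μ₁` solves the non-linear integral equation
  `μ₁ = μ₀ · 𝒢⁺(μ₀−μ₁) / (𝒢⁺(μ₀−μ₁) + 𝒢⁻μ₁)` (damped Picard iteration),
  collapsing to the closed form `μ₁ = √K⁺/(√K⁺+√K⁻) · μ₀` for local kernels.
* **macro** — the 1D cell-density equation

  (a+1) ∂ₜu = c₁ ∂ₓ(D(x) ∂ₓu) + ∂ₓ( u (θ c₁ D′(x) − χ 𝒜_r u) ),
  c₁ = 1/(2a+1) · d/(d+2),

  with the non-local adhesion velocity `𝒜_r u = ∇H_r ⋆ u`, no-flux
  boundaries, zero extension of the density inside the integral, and `θ`
  switching the myopic-diffusion drift on or off. The solver uses outer
  operator splitting (adhesion frozen per window of length `dt_outer` and
  interpolated linearly) with implicit trapezoidal inner steps on a
  conservative finite-volume stencil; mass is preserved to round-off.
  CAM-coupled (`∂ₓ(χ μ₁ 𝒜_r u)`) and hyperbolic-scaling transport variants
  are included.

## Worked example

Weak myopic diffusion with moderate adhesion on an initially uniform
population of 5 cells per unit length over (0, 6):

```python
from adhesim.macro import MacroConfig, solve_ibvp
from adhesim.diagnostics import detect_aggregates

cfg = MacroConfig(D0=0.15, delta=0.0, chi0=0.5, theta=1, T=25.0)
kymo = solve_ibvp(cfg, snapshot_stride=100)
agg = detect_aggregates(kymo.final(), threshold=5.0)
print("aggregates :", agg.count)
print("positions  :", [round(p, 2) for p in agg.peak_positions])
print("heights    :", [round(h, 1) for h in agg.peak_heights])
print("min spacing:", round(agg.min_spacing, 2))
print("mean level :", round(kymo.final().mass() / 6.0, 6))
```

prints

```
aggregates : 3
positions  : [1.16, 3.0, 4.84]
heights    : [380.2, 310.1, 397.6]
min spacing: 1.84
mean level : 5.0
```

Adhesion carves the uniform state into three tight aggregates spaced more
than one sensing radius apart, while the no-flux conservative scheme keeps
the spatial mean exactly at the initial level 5. Doubling the sensitivity
(`chi0=1.0`) roughly doubles the peak densities.

The same run from the shell:

```
adhesim macro --D0 0.15 --delta 0 --chi0 0.5 --theta 1 --out kymo.tsv
adhesim diagnose kymo.tsv
adhesim sweep --outdir sweep/        # full D0 x delta x chi0 x theta factorial
adhesim micro --preset two-cell --out traj.tsv
adhesim cam --local --Kplus 1 --Kminus 1 --mu0 5   # -> 2.5
```

Each command writes delimited-text output plus a JSON manifest that suffices
to reproduce the run.

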