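# Methods

## Model

The simulator evolves three fields on a 1-D tissue interval [0, L] with
no-flux boundaries:

* glioma cell density ρ(x, t) (cells/mm, capped by the tissue carrying
  capacity N),
* functional (perfused) tumour vasculature v(x, t), dimensionless in [0, 1]
  with normal tissue at v₀ = 1/2,
* oxygen concentration σ(x, t) (nmol/mm, physiological level σ₀).

Cells occupy one of two mutually exclusive phenotypes — migratory (hypoxic)
or proliferative (normoxic) — and interconvert with linear, oxygen-dependent
rates f₂₁(σ) = λ₁ − σ (proliferative → migratory) and f₁₂(σ) = λ₂σ.
Phenotype switching is assumed fast relative to migration and division, so
the phenotype split is slaved to the local oxygen:
α(σ) = (λ₁ − σ)/((λ₁ − σ) + λ₂σ) migratory, β = 1 − α proliferative. Only
the migratory subpopulation diffuses and only the proliferative one divides,
so summing the two phenotype equations puts the oxygen modulation *inside*
the diffusion operator:

    ∂ρ/∂t = ∂²[D_ρ α(σ) ρ]/∂x² + b_ρ β(σ) ρ (1 − ρ/N).

The composite-field (Fickian, "item diffusion") form follows from literal
summation of the two phenotype equations with ρ₁ = α(σ)ρ. The alternative
gradient-flux form ∇·(D_ρ α ∇ρ) is available behind the
`flux_form="gradient"` switch of the right-hand-side factory for sensitivity
checks; at the default parameters the two differ only inside the front where
∇α is appreciable, and none of the regime conclusions change.

Normalising D_ρ = D/α(σ₀) and b_ρ = b/β(σ₀) makes (D, b) the *intrinsic*
diffusion/proliferation rates: at σ ≡ σ₀ the system is exactly the classical
Fisher–Kolmogorov (Fisher–KPP) equation ∂ρ/∂t = D∂²ρ/∂x² + bρ(1 − ρ/N).

Vasculature forms logistically at rate g₁, gated by a Michaelis–Menten
response M = ρH̃(σ − σ̂)/(ρH̃(σ − σ̂) + Kv) to the quasi-steady
pro-angiogenic factor concentration: hypoxic cells (σ below the threshold
σ̂, realised by a smoothed decreasing step H̃ of steepness θ) produce the
factor proportionally to ρ, endothelial cells take it up proportionally to
v, and natural decay is negligible against uptake; the kinetic constants
collapse into the single half-saturation scale K. At the degenerate point
ρH̃ = 0, v = 0 we define M = 0 (no factor and no vessels means no
formation). Vaso-occlusion removes functional vessels at rate g₂vρⁿ — a
phenomenological power law for pressure-driven collapse; with the default
n = 6 the sink at ρ = N/2 is 2⁻⁶ = 1/64 of its value at ρ = N, so occlusion
is effectively confined to near-capacity regions without any hard threshold.
(An optional smooth gate H̃(N/2 − ρ) can be enabled but is off by default;
the power law alone reproduces the intended behaviour.)

Oxygen is supplied by functional vessels proportionally to the deficit from
σ₀ (rate h₁v) and consumed by cells by mass action (rate h₂ρσ — the only
form dimensionally consistent with h₂ in mm·cell⁻¹·day⁻¹).

Model hierarchy: **Model III** is the full system; **Model II** freezes the
vasculature (g₁ = g₂ = 0, v ≡ v₀); **Model I** additionally freezes oxygen
(h₂ = 0, σ ≡ σ₀), recovering Fisher–KPP. The solver enforces these limits
structurally (frozen fields are not integrated), and acceptance tests verify
that the limits agree node-wise with the full system run at the limiting
parameter values.

## Parameters

Defaults follow the glioma-modelling literature; ranged parameters take representative interior values:

| symbol | meaning | default | unit |
|---|---|---|---|
| D | intrinsic glioma diffusion | 2.73e-2 (range 2.73e-3…2.73e-1) | mm²/day |
| b | intrinsic glioma proliferation | 2.73e-3 (range 2.73e-4…2.73e-2) | 1/day |
| N | tissue carrying capacity | 100 | cells/mm |
| σ₀ | physiological oxygen | 1.0 | nmol/mm |
| λ₁ | switching (prolif→migr) | 2.0 | nmol/mm |
| λ₂ | switching (migr→prolif) | 1.0 (set {0.5, 1, 2}) | – |
| D_σ | oxygen diffusion | 151 | mm²/day |
| h₁ | oxygen supply rate | 0.337 | 1/day |
| h₂ | cell oxygen consumption | 5.73e-3 (range 5.73e-3…1.14e-1) | mm/(cell·day) |
| D_v | vasculature dispersal | 5e-4 | mm²/day |
| g₁ | vessel formation rate | 0.1 | 1/day |
| σ̂ | hypoxic threshold | 0.25 | nmol/mm |
| K | half-max pro-angiogenic factor | 1.0 | nmol/mm |
| g₂ | vaso-occlusion rate | 5e-12 (range 5e-13…1.5e-11) | mmⁿ/(cellⁿ·day) |
| n | occlusion degree | 6 | – |
| θ | Heaviside steepness | 0.01 (= 1% of σ₀) | nmol/mm |

D and b default to the geometric midpoints of their two-decade spans; h₂
defaults to 5.73e-3, the value at which the vaso-occlusion maps are
computed, and g₂ to the middle of its literature set. λ₁ > σ₀ is enforced so
f₂₁ stays positive for all admissible oxygen levels.

Run settings (no literature consensus exists; all are config-exposed): domain L = 200 mm, nx = 2001 nodes (dx = 0.1 mm),
final time T_f = 400 days, outputs every 10 days. Initial condition: a
smoothed indicator of [0, ε] with ε = 2 mm, steepness γ = 0.1 mm, amplitude
ρ₀; v ≡ v₀ = 1/2, σ ≡ σ₀.

**Seed density ρ₀ = 0.1N.** The occlusion sink at the seed must be
negligible over the horizon (g₂v₀ρ₀ⁿT_f ≪ 1, i.e. ρ₀ ≲ 0.15N at the largest
literature g₂), otherwise the initial condition itself occludes vessels in
every tumour and the low-proliferation regime — tumours that never reach
occlusive densities and are therefore insensitive to g₂ — cannot exist. A
seed at 10% of carrying capacity satisfies this with margin and is a
conventional seeding density for Fisher–KPP-type glioma simulations.

## Numerics

Method of lines: 3-point central second differences; zero-flux boundaries by
ghost-node reflection (which makes the trapezoid-weighted total mass exactly
conserved by the discrete diffusion operator). Fields are interleaved per
node so the Jacobian is banded with bandwidth equal to the number of evolved
fields; time integration is LSODA (adaptive, stiffness-switching) with
rtol = 1e-6, atol = 1e-9 and analytic band structure declared. Stiffness
comes from fast oxygen relaxation (h₁v + h₂ρ up to ~1/day against cell time
scales of hundreds of days, and D_σ/dx² ≈ 1.5e4/day).

Degenerate and out-of-range inputs: σ is clamped to [0, λ₁ − 1e-12] before
the switch fractions are evaluated inside the right-hand side (adaptive
solvers probe transiently inadmissible states); at output times, negative
excursions within the integrator's error floor (1e-8, ~10× atol) are clipped
to zero and anything larger — or overshoot above a field's upper bound
beyond 0.1% — raises a typed integration error with the offending time. A
run is bit-reproducible for fixed inputs and library versions; there is no
randomness anywhere.

Front position is the argmax of the descending gradient right of the density
maximum, refined by quadratic interpolation over three neighbouring gradient
values; front speed is the least-squares slope over the final 25% of output
times (at least four points required), erroring out if the front enters the
last 5% of the domain. Infiltration width interpolates the 80% and 2%
crossings of the profile maximum linearly on the monotone front segment.
D_eff and b_eff are unweighted domain averages of D_ρα(σ(·, T_f)) and
b_ρβ(σ(·, T_f)) by trapezoidal quadrature (a ρ-weighted variant exists
behind the `density_weighted` flag; it emphasises the tumour bulk and was
not used for any reported number).

**KPP speed comparisons use T_f = 1000 days.** Pulled fronts approach the
minimal speed 2√(Db) like c(t) ≈ c − 3/(2λt) with λ = √(b/D); at
T_f = 400 days the measured speed is still ~7% low for b ≈ 0.0273/day,
whereas by T_f = 1000 days the gap is ~3%, inside the 5% comparison band.
The domain is enlarged proportionally (L ≈ 1.35·c·T_f) to keep the wave
clear of the boundary.

## Response maps and thresholds

Sweeps run every (D, b, level) cell as an independent, identically
configured integration (cell failures carry typed markers, never silent
defaults; rerunning a sweep is bit-identical). Difference maps subtract
consecutive levels of the varied parameter. A speed change below 0.5% of the
cell's base speed counts as "no change" (dead zone absorbing numerical
error); threshold estimators work on sign brackets, never interpolated zeros
of noisy differences.

* b\* (oxygen-consumption maps, Model II): per D column, the sign of the
  speed change flips from positive (low b: hypoxia-boosted migration wins)
  to negative (high b: lost proliferation wins); the flip is bracketed
  between adjacent grid values and the median bracket across columns
  reported with its spread.
* b⁺ and Λ⁺ (vaso-occlusion maps, Model III): b⁺ is the smallest b whose row
  contains a cell that speeds up; within rows b ≥ b⁺ the sign boundary along
  D is located, its log-midpoints collected, and the line b = Λ⁺D fitted in
  log space (unit slope). Fewer than three boundary points raises an
  insufficient-resolution error; the fit residual is reported in units of
  the b-grid cell.

Routine map resolution is 8×8 log-spaced cells over the literature two-decade
(D, b) ranges. The vaso-occlusion boundary needs finer sampling to yield at
least three boundary points, so the Model III map is computed at 12×12
(≈3 minutes on one CPU); the Model II map stays at 8×8 (≈1.5 minutes).

## What the tests do and do not show

All inputs are generated programmatically (analytic profiles, parameter
grids); there are no measured data. Passing tests therefore demonstrate
internal consistency of the model and numerics — closed-form oracles
(Fisher–KPP speed, uniform oxygen fixed point, tanh-profile width
inversion), exact structural limits (hierarchy, conservation, bounds), and
the emergent regime structure (monotone D_eff/b_eff/width shifts, existence
and bracketing of b\*, b⁺, Λ⁺) — not agreement with any biological
measurement. Real gliomas grow in 3-D heterogeneous, anisotropic tissue with
necrosis, immune involvement and treatment effects, none of which are
modelled.

## Known limitations

* The width trade-off across Λ⁺ is asymmetric in this parameterisation:
  above Λ⁺ every responding cell is slower *and* wider, but below Λ⁺ the
  width *reduction* accompanies the speed-up only in the fastest-front cells
  (highest D at b ≥ b⁺); in the remaining speed-up cells the width still
  grows slightly. The oxygen deficit spreads ~√(D_σ/(h₁v₀)) ≈ 30 mm ahead of
  the front, widening fronts across most of the plane. Acceptance asserts
  the regime structure (opposite speed signs across the fitted boundary,
  both trade-off types non-empty) rather than a strict cell-wise width sign.
* Cells within one grid step of the fitted Λ⁺ line are not classified — the
  boundary is only resolved to the grid (fit residual < 1 cell).
* Threshold estimates are implementation-anchored: no reference numeric
  values exist for b\*, b⁺ or Λ⁺, so they are validated structurally
  (existence, sign pattern, stability under grid refinement), not compared
  to reference numbers.
* 1-D geometry only; higher-dimensional extensions would require the radial
  symmetry assumption to hold.
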