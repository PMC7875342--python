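# Methods

## Model

`gliofront` integrates a five-species system on a 1D transect through a
glioblastoma invasion front, Ω = [0, 1] in domain units with migration
toward +x.  One domain unit is read as ≈ 100 cell diameters
(`cell diameter = 0.01` units), times are hours, and all densities are
scaled: tumor density N and ECM E to their respective reference levels
(K_N and E0), integrins to the membrane saturation level K_I.

Assumptions baked into the model:

* **Sharp-front transport.** Tumor and protease fluxes are flux-saturated:
  J = ν u uₓ / √(m² + (ν/v)² uₓ²).  For small gradients this is the
  porous-medium flux (ν/m) u uₓ; for steep gradients |J| ≤ v·u, so the
  support edge cannot move faster than v.  The square-root denominator is
  the standard flux-limited form; it is the only choice that yields the
  bounded-speed property, which is the point of the mechanism.
* **Front-localised biochemistry.** The tumor support Sup(N) = [0, b_N]
  is detected as the rightmost crossing of δ_N (linear interpolation
  between nodes); the microtube band L_TM = [b_N, min(b_N + h_p, 1)]
  hosts MMP1 production.  The activity functional
  F(N) = (moving integral of N over [x−h_p, x+h_p] + ε)^(−α_F)
  concentrates production and integrin activation where local tumor mass
  is low, i.e. at and ahead of the edge.  The moving integral is computed
  exactly for the piecewise-linear interpolant of N and truncated at the
  domain boundaries (no tissue outside Ω; zero-padding would inflate F at
  the walls).
* **Taxis saturation.** Chemo-/haptotactic drift is a·gₓ/(1+gₓ²): bounded
  by a/2, vanishing again on near-discontinuous cues.
* **ECM floor.** ECM decays as −a₆ (E − E_basal χ_Sup) P: a smooth
  relaxation to the residual matrix level observed inside tumor bulk,
  reducing to plain −a₆ E P outside the support (and everywhere when
  E_basal = 0).
* **Integrin bookkeeping.** Activation a₇ E I F and inactivation
  a₈ A χ_Sup exchange the two pools exactly (dA + dI contains only the
  exocytosis term a₉ (K_I − A − I) on Sup ∪ L_TM; the union avoids double
  production at the shared point b_N).  Basal levels (A_basal in the
  bulk, I_basal on the band) enter through the initial condition, not
  through sources.
* **Transport orientation.** The integrin transport term is written
  +v_Int ∂x in the literal equations, which advects leftward for a
  rightward-migrating front.  Since its stated purpose is to carry the
  membrane-bound pools toward the front, the default orientation is
  "toward_front" (rate −v_Int ∂x, upwinded); the literal sign is
  available as `transport_orientation="as_printed"`.

## Default parameters

All defaults are this package's own calibration — chosen once so that the
baseline run is in the regime the model is built for, and shipped as a
versioned configuration.  They are not a fit to any dataset.

| symbol | default | units | role / why this value |
|---|---|---|---|
| ν_N, m_N, v_N | 0.008, 1, 0.02 | —, —, units/h | tumor mobility; v_N = 0.02 lets the front cross ~0.3 of the domain in 15 h; ν_N small enough that the growth-driven tail speed √(a₃ν_N K_N/2m_N) ≈ 0.006 stays well below v_N (speed stays saturation-limited) |
| a₁, a₂ | 5·10⁻⁴ each | units/h | taxis adds at most (a₁+a₂)/2 = 5·10⁻⁴ to the front speed (2.5% of v_N) in the baseline |
| a₃, K_N | 0.01, 1 | 1/h, — | slow glioma proliferation; K_N sets the density scale |
| ν_P, m_P, v_P | 0.02, 1, 0.04 | | proteases spread faster than cells |
| a₄, a₅ | 0.5, 0.4 | 1/h | band-gated production vs. bulk degradation give a P halo ahead of b_N with basal bulk levels |
| a₆, E0, E_basal | 0.5, 1, 0.1 | 1/h, —, — | ECM degradation and the residual bulk matrix |
| a₇, a₈, a₉, K_I | 3, 1, 3, 1 | 1/h | activation/exocytosis fast relative to the band transit time h_p/v_N = 3 h, so A equilibrates into a plateau on the band |
| v_Int | 0.02 | units/h | integrin transport rides with the front (≈ v_N), which keeps the band profile quasi-stationary in the co-moving frame |
| h_p | 0.06 | units | microtube reach: 6 cell diameters ahead of the edge |
| ε, α_F | 0.3, 1 | — | activity contrast ≈ 3× between front and bulk without a singular limit |
| δ_N | 10⁻³·K_N | — | support detection threshold, robust to float noise at the foot |
| A_basal, I_basal | 0.2, 0.4 | — | basal active pool in the bulk / inactive pool on the band |

The splitting demonstration uses the same configuration with a₄ = 1,
a₅ = 4 (MMP1 — and hence the chemotactic pull — concentrated at the
front) swept over a₁: at a₁ = 0.2 the shoulder detaches from the bulk and
the tumor breaks into two super-threshold components by t = 3 h, while
the baseline a₁ keeps a single connected front throughout.  The porosity
variant maps ECM to porosity ε(x) = 0.50 + 0.16·(1 − E/E0) and ramps v_N
smoothly (cubic smoothstep) from v_N at 50% porosity to 1.6·v_N at 66%.

## Numerics

* **Space:** mass-lumped linear-element Galerkin on a uniform 500-node
  grid — algebraically a conservative finite-volume stencil with fluxes on
  faces and no-flux boundaries.  Face mobilities use the arithmetic mean
  of the nodal values (exact for the quadratic porous-medium nonlinearity);
  face gradients are the one-cell difference.
* **Time:** IMEX.  N and P: mobilities and tactic drifts frozen at the
  current state (one Picard refresh configurable), the linear
  transport operator inverted implicitly — a tridiagonal M-matrix solve,
  hence unconditional positivity and exact mass conservation of the
  transport part; MMP1 degradation is folded implicitly into the same
  solve, production is explicit; logistic growth uses its exact solution
  map (operator splitting).  E, A, I: classical RK4 with the advection
  upwinded inside the right-hand side; the explicit advection CFL
  v_Int·dt/dx is checked before stepping.  Default dt = 1.5·10⁻⁴ h
  (10⁵ steps over 15 h) — the desk-scale resolution; finer settings are a
  config choice.
* **Regions:** Sup(N), L_TM and F(N) are refreshed every step; indicator
  functions are evaluated sharply on nodes.  A measure-zero band (front
  at the wall) produces nothing.
* **Degenerate inputs:** an empty support disables every χ-gated source
  and the simulation proceeds; negative intermediate values in the RK4
  subsystem are floored at zero and counted (zero events at the default
  resolution in all shipped scenarios); non-finite values abort with the
  step index and field name.
* **Initial state:** plateau at K_N with a tanh shoulder of *physical*
  width 0.005 units (≈ 2.5 cells at 500 nodes).  A physical width rather
  than a cell count keeps the initial profile identical across grid
  resolutions, which is what makes grid-convergence comparisons of the
  front position meaningful.
* **Front metrics:** peaks by leftmost argmax with parabolic refinement
  (only when both neighbours are strictly lower); front width is the
  0.9→0.1 relative-level distance on the leading side; the
  active/inactive exchange position is the argmax of
  |a₇ E I F − a₈ A χ_Sup|.
* **Accuracy at the front:** the first-order scheme smears the sharp edge
  over a few cells, which biases the measured δ-crossing speed a few
  percent above v_N at 500 nodes (flux limiters and adaptive meshes are
  out of scope); the shipped regime keeps the total measured speed within
  2% of v_N and the 500-vs-1000-node front position within 1% at 5 h.

## Synthetic line scans

The profiles module emulates multi-channel fluorescence line scans
(membrane / MMP1 / FAK / Talin): Gaussian bumps or dips with per-channel
center, width, amplitude and baseline, plus additive zero-mean Gaussian
noise clipped at zero intensity, deterministic per seed.  What it does
*not* emulate: correlated (speckle) noise, photobleaching drift, saturated
pixels, non-Gaussian peak shapes, or registration error between channels.
Passing tests therefore demonstrate the estimator pipeline (smoothing,
peak refinement, ordering fraction, windowed correlation) under a clean
noise model, not performance on raw microscopy data.

Smoothing is a weighted discrete spline: minimise Σ wᵢ(yᵢ−fᵢ)² +
λ·dx·Σ((Δ²f)/dx²)², solved as a pentadiagonal system on the residual
about the weighted least-squares line (the penalty nullspace), so affine
data are reproduced exactly for every λ and the λ→∞ limit is the weighted
line to machine precision.  λ = 0 is the identity.  The default
λ = 10⁻⁸ (position⁴ units) preserves noiseless bump positions to within
one sample spacing at the default 200-sample design; an optional GCV
selector (`gcv_lambda`) scans a logarithmic grid.  Weights default to
uniform; any positive per-sample weighting can be supplied.

## Known limitations

* 1D only; no curvature, branching, or 2D front morphology.
* First-order front capturing (see above); production-grade resolution of
  the shock structure needs finer grids than the desk default.
* The proliferation term is fixed logistic; heterogeneous-proliferation
  variants are only reachable by swapping the growth map in user code.
* The porosity→speed ramp shape between its two anchor points (smoothstep)
  is a modelling choice; only the anchors and monotonicity are
  constrained.
* Parameter defaults are a calibrated reference configuration, not
  estimates with uncertainties; sensitivity analysis is left to the user
  (the sweep machinery helps).
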