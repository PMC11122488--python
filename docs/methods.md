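# Methods

## Scope and model reduction

`stentdeg` couples a multifactor hydrolysis model of PLA to a reduced
structural model of the stent. The reduction choices, relative to a full
3-D solid-element treatment, are:

- **Struts as beams.** Stent struts (200 µm × 150–170 µm sections) are
  slender; they are modelled as corotational Euler–Bernoulli beams with a
  Gauss–Legendre fiber grid over the rectangular section (default 4 × 4;
  area and inertia integrate exactly) and elastic–perfectly-plastic
  fibers. The reported element stress is the maximum fiber |axial stress|
  — the beam-model proxy for von Mises — and never exceeds the current
  yield strength.
- **Crimp plates as a rigid cylinder.** The circumferential crimp plates
  tile the circumference and only the total radial force is of interest,
  so they are idealized as an axisymmetric rigid cylinder with penalty
  contact (default 10⁴ N/mm per node; observed penetrations are µm-scale
  against a 10⁻² mm tolerance). Friction is omitted in this axisymmetric
  idealization.
- **Balloon as applied pressure, artery as a closed-form tube.** The
  balloon acts only during the short deployment and is replaced by a
  trapezoidal pressure on the strut inner faces. The artery is an
  incompressible plane-strain Mooney–Rivlin thick-walled tube
  (W = C10(Ī₁−3) + C01(Ī₂−3); C10 = 1.023, C01 = 0.710 MPa; 3.0 mm lumen,
  0.4 mm wall): its inflation pressure P(λ) = ∫ (σθ−σr)/r dr is
  precomputed by quadrature and applied to stent nodes through tributary
  areas as a radial foundation. Axial tethering of the vessel is ignored.
- **Quasi-static implicit solve.** Crimping, deployment and the daily
  degradation equilibria are solved implicitly (Newton with load-step
  bisection), which avoids the kinetic-energy artifacts an explicit
  dynamic solver introduces into what is a quasi-static problem.

## Degradation model

Per material point (default 4 per beam element, each owning an equal share
of the element volume):

- **Scission.** β' = β·e^{−λΔt} each macro-step (exact for frozen λ), with
  λ = λ₀[e^{bσ} + C_m + α_v − 1]. λ₀ = 0.003 day⁻¹; the stress
  sensitivity b ≡ B/RT is not an independently tabulated constant — the
  default 0.02 MPa⁻¹ places one e-fold of acceleration at the 50 MPa
  yield strength and is echoed in every run log. Two alternative parses
  of the rate law are selectable (`rate_form="exp_all" | "mixed"`); the
  `mixed` form is dimensionally inconsistent and kept for comparison only.
- **Hydrolysate reaction–diffusion.** ∂C/∂t = ∇·(φ∇C) + S − k_rel·C on
  the strut graph: 1-D conduction along struts (conductance φA/d, harmonic
  mean of point diffusivities), junctions joined by the exact star-mesh
  transform so the operator is symmetric and conserves mass to round-off.
  φ = φ₀e^{θ(1−β)} with φ₀ = 1.2×10⁻³ mm²/day and θ = 9.43 (a ×12 453
  amplification at full degradation). The source S = s₀·(−Δβ)/Δt ties
  hydrolysate production to scission (s₀ = 1 by normalization); washout to
  blood is first-order with k_rel = 0.2 day⁻¹, chosen so C_m stays O(10⁻²)
  in thin struts; set k_rel = 0 for closed-system tests. The explicit
  update sub-steps automatically to 40 % of the stability limit.
- **Swelling.** α_m(t) = α_m∞(1 − e^{−t/τ}) with α_m∞ = 0.1, τ = 7 days —
  first-order water uptake saturating within ~3 weeks, giving
  α_v∞ = 1 + 1.2·0.1 = 1.12 with the dry/water density ratio. These two
  values are the model's own choice (no standard kinetics exist for
  stent-scale samples); under the default calibration they produce the
  characteristic rise-then-fall of residual volume with a peak near day
  20–25.
- **Death.** A point dies when β < β_thre = 0.01 or when a uniform draw
  falls below 1 − e^{−kλΔt} (the exact one-step integral of the scission
  hazard kλe^{−kλt}; k = 0.12). One independent draw per alive point per
  day; runs are bit-reproducible for a given seed. Dead points freeze
  (β, C_m, α_v retained), are excluded from diffusion and from the β̄/σ̄/v_r
  statistics, and keep the water modulus in the stiffness — they are never
  deleted.
- **Material laws.** σ_y(t) = η·σ_y0·e^{−ϕ∫λdτ} (σ_y0 = 50 MPa, ϕ = 1.225,
  trapezoidal accumulation of the *local instantaneous* λ), with η = 0.99
  applied as a constant fatigue knock-down from t = 0 — the cyclic
  pulse amplitude enters the daily loop only through η, while the daily
  mechanical load is the cycle-averaged pressure. E(β) uses the saturating
  form (E_s0−E_water)(e/(e−1))(1−e^{−β}) + E_water (endpoints exact); an
  equivalent exponential form is available by configuration.

## Geometry

Supporting rings are sinusoids of amplitude h wrapped on the nominal
3.0 mm cylinder, alternating phase so each peak faces a valley of the next
ring; connectors join n_connectors equally spaced facing crown pairs
(straight chords, single-period wavy sinusoids, or peak-to-valley
diagonals). Neither crown counts nor h are published for the commercial
devices: the defaults are 6 crowns per ring for all four families (the
smallest count divisible by both 3 and 6 connectors, which preserves exact
rotational symmetry by one connector pitch) and h = 0.8 × axial ring
pitch, which gives the Igaki-Tamai/Fantom family its characteristically
larger ring amplitude (their 6 rings over 10 mm vs 11 over 10.5 mm).
Both are configurable. Lattices are deterministic functions of the design
parameters; total material-point volume equals the analytic strut volume
to 10⁻⁹ relative.

## Numerical choices

- Newton tolerance: residual < 10⁻⁸ × load norm with a 10⁻⁷ N floor.
  Fully yielded sections make the consistent tangent singular; the tangent
  (only) uses 10⁻⁴E hardening, and an Aitken-style extrapolation
  accelerates the resulting linear convergence. When a buckled,
  contact-dominated configuration stagnates (a near-mechanism state), the
  solve is accepted at the better of 10⁻³ N or 1 % of the load norm and
  flagged in the diagnostics.
- Snap-through during crimping (pronounced for the sparsely connected
  Absorb lattice, which deforms irregularly under crimp) is traversed
  with weak stabilization springs (0.05 N/mm) anchored at the last
  converged step, released for the final equilibrium.
- Crimp radial stiffness is the least-squares slope of the force–diameter
  curve over the first 10 % of the diameter travel (configurable).
- Degradation uses Δt = 1 day macro-steps. A sub-daily mode is available
  for small fixtures by shrinking `KineticParams.dt`.
- Default problem sizes: 3-ring segments (≈130 nodes, ≈145 elements,
  ≈580 material points) for degradation studies, chosen as the smallest
  segment containing interior rings; full lattices for crimping studies
  where the cross-design force ordering is of interest. A coupled 180-day
  3-ring run takes seconds; a full-device crimp, minutes.

## What the built-in designs do and do not show

Under the default calibration the model reproduces the qualitative
cross-design picture: identical radial stiffness within each
supporting-ring family, the DESolve lattice stiffest in crimp with the
highest peak radial force, roughly double the crimp recoil for the
large-amplitude Igaki-Tamai/Fantom family, deployment of all four designs
into the 3.0–3.4 mm band within the clinical 1.0–1.1 expansion-ratio
window, residual volume peaking near day 22, and a 40–50 % molecular
weight loss at 180 days. It does **not** reproduce absolute crimp forces
or the published day-180 index values of the commercial devices, which
depend on solid-element stress concentrations at the crown bends and on
constants (B/RT, S(t), α_m(t), balloon pressure) that have no published
values; in particular the day-180 β̄ *ordering* across designs can invert,
because in the beam reduction the deeper-expanding large-amplitude
designs retain more residual stress than their solid-element counterparts.
The acceptance script reports the measured values so this comparison is
explicit.

## Limitations

- Bulk erosion only; no surface-erosion discrimination, no explicit pH
  chemistry, no layered vessel wall.
- η is a single constant; no per-cycle fatigue damage accumulation.
- The vessel foundation is elastic and memoryless (no remodeling, no
  viscoelasticity); blood pressure loads the stent directly, while shear
  effects of flow on degradation are neglected.
- Torsional fiber plasticity is not modelled (elastic GJ torsion).
- The scoring system uses equal indicator weights by default; weights are
  configurable but no quantitative weighting is implied.
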