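# Methods

This note records the modeling assumptions, parameter meanings, numerical
choices and known limitations of `bonevpd`. It states no result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Constitutive model

The model describes a bone material point under small strain.  Stress is
carried in MPa, time in seconds; Voigt order is (11, 22, 33, 12, 23, 31)
with engineering shear in strain vectors.  Four coupled mechanisms:

1. **Damaged orthotropic elasticity.**  σ = (1 − D(κ)) 𝕊 (ε − εᵖ).  The
   compliance is assembled from nine engineering constants; the
   off-diagonal for each normal-strain pair is the listed Poisson ratio
   divided by the modulus of that pair's distinguished axis: −ν₁₂/E₁,
   −ν₂₃/E₂ and −ν₃₁/E₁.  The last placement deserves a remark: with the
   31-pair ratio referenced to E₁ (i.e. ν₃₁ plays the role of ν₁₃, as in
   common FE input conventions), the presets with E₂ = E₃, G₁₂ = G₃₁ and
   ν₁₂ = ν₃₁ are exactly transversely isotropic about axis 1, which is the
   physically intended symmetry for cortical and trabecular bone.
   Referencing it to E₃ instead would break the 2↔3 exchange symmetry of
   the assembled matrix.  Positive definiteness of the stiffness is
   verified at construction and inadmissible constants are rejected.

2. **Scalar damage.**  D(κ) = 1 − e^(−k_p(κ−k₀)) for κ ≥ k₀, zero below.
   κ is the time integral of the plastic strain-rate tensor norm (weights
   (1,1,1,½,½,½) on squared engineering-shear Voigt components), so it is
   non-negative and non-decreasing by construction, and D ∈ [0, 1) always.
   The activation threshold k₀ models the experimental delay between
   plastic-strain onset and microcrack onset.  Damage is isotropic — a
   deliberate trade of directional fidelity for identifiability from
   uniaxial tests.

3. **Yield surface.**  Y(σ, κ) = √((σ − r(κ)A) : 𝔸 : (σ − r(κ)A)) − r(κ).
   The square root makes Y dimensionless and degree-1 homogeneous about
   the centre, matching the dimension of the overstress function φ(γ).
   A and 𝔸 are assembled from uniaxial yield strains by a centred-quadric
   construction: yield stresses σ₀ᵢ± = Eᵢ ε₀± on each material axis, shear
   yield stresses τ₀ᵢⱼ = Gᵢⱼ √(ε₀⁺ ε₀⁻) (a geometric-mean rule, since no
   separate shear yield strain is calibrated), classical quadratic
   coefficients Fᵢᵢ = 1/(σ₀ᵢ⁺σ₀ᵢ⁻), linear terms Fᵢ = 1/σ₀ᵢ⁺ − 1/σ₀ᵢ⁻,
   normal-normal interaction Fᵢⱼ = −ξ₀ √(Fᵢᵢ Fⱼⱼ); the quadric
   σ:F:σ + F⃗·σ = 1 is then re-centred, A = −½F⁻¹F⃗ (on the normal-stress
   subspace) and 𝔸 = F/(1 + A:F:A).  The construction is validated at
   build time — all six uniaxial calibration states must lie on Y = 0
   within 10⁻⁸ — rather than trusted; an interaction coefficient that
   makes the quadric indefinite (non-convex surface) is rejected.  Fabric
   vectors m₁, m₂, m₃ define the material frame; for non-identity frames
   the tensors are assembled in the material frame and pulled back through
   the Voigt stress rotation.

   A consequence of the strong tension–compression asymmetry of the
   presets (ε₀⁻/ε₀⁺ ≈ 8 for cortical bone) is that the centre A sits far
   on the compressive side (≈ −263 MPa on axis 1 for cortical), so the
   surface is shallow near the tension vertex: dσ₁₁/dY there is several
   hundred MPa per unit Y.  Small overstresses therefore translate into
   sizable stress excursions above the rate-independent curve — the model
   is strongly rate-sensitive in tension even though η is small.

4. **Hardening/softening and Perzyna viscosity.**  r(κ) saturates from 1
   towards y_r with rate s_h and, in the default `softening` mode, decays
   exponentially (rate s_s) past the onset k_s, continuously.  The
   `original` mode keeps the monotone branch everywhere; the two modes are
   selectable per call so the contrast (post-peak decay vs monotone
   response) can be reproduced.  Plastic flow is associated,
   ε̇ᵖ = γ ∇_σY, with γ = (Y² + mY)/η; its exact inverse
   φ(γ) = −m/2 + √(m²/4 + ηγ) defines the generalized yield
   Ȳ = Y − φ(γ) used by the integrator, and the generalized Kuhn–Tucker
   conditions Ȳ ≤ 0, γ ≥ 0, γȲ = 0 hold at every converged state.

## Parameters

| block | symbol | unit | cortical | trabecular | role |
| --- | --- | --- | --- | --- | --- |
| elastic | E₁, E₂=E₃ | MPa | 19900, 11200 | 280, 160 | axial/transverse moduli |
| | ν₁₂=ν₃₁, ν₂₃ | – | 0.3, 0.4 | 0.22, 0.48 | Poisson ratios |
| | G₁₂=G₃₁, G₂₃ | MPa | 5700, 4300 | 80, 60 | shear moduli |
| damage | k₀ | – | 10⁻⁴ | 10⁻⁴ | activation threshold (κ) |
| | k_p | – | 5 | 5 | damage rate |
| hardening | y_r | – | 5 | 5.5 | saturation ratio |
| | s_h | – | 10.5 | 20 | hardening rate |
| | k_s | – | 0.01 | 0.005 | softening onset (κ) |
| | s_s | – | 1.5 | 4.5 | softening rate |
| viscosity | m | – | 5 | 5 | overstress shape |
| | η | s | 0.01 | 0.01 | viscosity |
| yield | ε₀⁺, ε₀⁻ | – | 0.0018, 0.015 | 0.005, 0.0075 | uniaxial yield strains |
| | ξ₀ | – | 0.25 | 0.25 | interaction coefficient |

Cortical moduli are stored in MPa (converted from GPa table entries at
transcription).  The `reduced` preset variant replaces the yield strains
with their equilibrium values — the calibrated strains scaled by the 0.24
mean relaxation-reduction fraction (cortical ε₀⁺ carries one extra digit
of published rounding: 0.00044 rather than 0.000432).

## Return-mapping integrator

Each strain-driven step computes the elastic trial
σ_t = (1 − D(κₙ)) 𝕊 (ε − εᵖₙ); if Y(σ_t, κₙ) ≤ 0 the trial is accepted
as elastic.  Otherwise Newton–Raphson solves the 8-dimensional system
b(x) = [Ȳ; R; h] = 0, x = [σ, γ, κ], from x₀ = [σ_t, 0, κₙ]:

* R = 𝔼σ_t/(1 − D(κₙ)) − 𝔼σ/(1 − D(κ)) − Δt γ ∇_σY with 𝔼 the
  *undamaged compliance*, i.e. a strain-dimensioned residual.  Under this
  reading the trial state zeroes R and h exactly, and a converged state
  satisfies the damaged-elastic law and the flow rule simultaneously
  (cross-checked in the tests to 10⁻⁸).
* h = κₙ − κ + Δt γ |∇_σY|, with the tensor-consistent norm above.
* Convergence requires res = Ȳ² + ‖R‖² + h² < tol₁ = 10⁻⁶ **and**
  |Ȳ| < tol₂ = 10⁻⁸.  In practice the analytic Jacobian converges in 2–3
  iterations to residuals near machine precision.

Numerical choices: damage is evaluated at the *unknown* κ inside the loop
(consistent with the elastic law), not frozen at the step start; the
hardening and damage formulas are analytically continued to transient
negative-κ Newton excursions; φ'(0) = η/m is finite so no regularization
is needed at γ = 0; the Jacobian is analytic by default with a central
finite-difference mode (relative perturbation 10⁻⁷) retained as a
cross-check and fallback; a singular Jacobian or iteration-cap overrun
raises a convergence error carrying the last residual, and the drivers
respond by bisecting the strain increment (up to 10 levels).  Converged γ
or κ below their lower bounds by more than 10⁻¹⁰ is an error; smaller
round-off excursions are clamped.

## Drivers

* `run_strain_path` imposes all six strain components (ramp or sawtooth on
  one axis).
* `run_uniaxial` is mixed-control: axial strain imposed, the two lateral
  normal strains solved per step by an inner two-unknown Newton (finite
  difference Jacobian, elastic closed-form first guess, then linear
  extrapolation) until the transverse normal stresses vanish within
  10⁻⁶ MPa.  Shear components remain identically zero, which is exact for
  fabric-aligned loading.
* `run_relaxation` ramps uniaxially (mixed control) and then freezes the
  full strain vector; during the hold the overstress relaxes and the
  stress decays monotonically toward the rate-independent state.  The
  default hold schedule grows the time step from 10 s to 500 s over a
  10⁴ s observation window.  An elastic ramp triggers a warning (elastic
  states carry no overstress, so the hold is exactly constant).

Experiment design for the limiting-behaviour checks: because of the
shallow tension vertex noted above, the viscous and inviscid curves only
coincide when loading is quasi-static.  The rate-independent-limit
experiment therefore ramps at 10⁻⁴ 1/s and the relaxation-structure
experiment at 2.5·10⁻⁵ 1/s — rates at which the Perzyna overstress is a
sub-percent perturbation — while the calibration-style runs keep the
1 s / Δt = 0.01 s schedule, where rate sensitivity is intentional and
verified (faster ramps give higher peak stress).

## Relaxation calibration

Normalized relaxation records s(t) are fitted as s = a·t^(−b) by linear
least squares in log–log space (scale-equivariant; reported residual sum
of squares is in log space).  A pure power law has no finite nonzero
asymptote, so the "asymptotic" percentage reduction is operationalized at
a 10⁶ s horizon relative to a reference time:
100·(1 − (horizon/t_ref)^(−b)), clipped to [0, 100].  The nine published
per-curve reductions average 24.33%, rounded to the whole-percent 24%
before use; the resulting fraction 0.24 *multiplies* the calibrated yield
strains to produce the equilibrium set (the naming "reduction" refers to
the stress drop, not to the scaling factor's complement).

## Octree axes assignment

The orientation cloud carries one right-handed orthonormal triad per
point.  The octree root is the tight bounding cube (edge = largest
extent); leaves hold at most `capacity` points (default 8 — a compromise
between tree depth and per-leaf scan cost; the quadtree illustrations of
such structures typically use 2, and all capacities in {1, 2, 8, 32} are
tested); the recursion depth is capped at 21 so duplicate-point clouds
terminate, allowing leaf overflow only at the cap.  Points on an internal
splitting plane belong to the lower octant (half-open boxes), so every
point is indexed exactly once.  Search prunes subtrees whose box distance
exceeds the current best, ties resolve to the smallest cloud index
(matching the exhaustive-scan oracle bit for bit), and efficiency is
asserted by counting distance evaluations, never by wall-clock timing.
Assigned triads are re-orthonormalized through the polar factor (SVD),
with a det = −1 factor corrected by flipping the third axis.  Triads are
carried as data: no interpolation or averaging between neighbours.

## Synthetic fixtures

The generators are pure functions of their arguments and a seed.

* Relaxation series: log-spaced times on [1, 10³] s with multiplicative
  Gaussian noise — emulating the sampling and scatter of digitized
  literature relaxation curves, not any specific instrument.
* Orientation clouds: analytic frame fields (uniform; a cylindrical shell
  r ∈ [8, 10] mm, z ∈ [0, 10] mm with circumferential/radial/longitudinal
  axes; a 270° torus segment) at mandible-like millimetre scale.  The
  cylindrical cloud at n = 10⁴ has nearest-neighbour spacing ≈ 0.5 mm,
  giving sub-2° typical angular offsets — ground truth tight enough for a
  5° fidelity check.  Real CT-derived clouds add noise, outliers and
  anatomical curvature discontinuities that these smooth fields do not
  emulate, so passing the fidelity check demonstrates correctness of the
  assignment, not robustness to imaging artefacts.
* Strain programs: ramp/sawtooth over 1 s in uniform increments by
  default (Δt = 0.01 s at 100 steps), ramp-and-hold with the growing
  10→500 s hold schedule.

## Known limitations

* Small-strain kinematics only; no finite-element coupling (no consistent
  tangent export) — the drivers are material-point experiments.
* Damage is scalar and uncoupled from the softening branch; there is no
  healing/remodeling, so long-time damage predictions saturate
  unrealistically high.
* The yield-tensor construction from uniaxial yield strains (geometric-mean
  shear rule, centred Tsai-Wu quadric) is validated only against the six
  uniaxial calibration states and the ξ₀-symmetry; multiaxial yield data
  would be needed to discriminate it from alternative fabric-based
  constructions.
* The specimen-level experiments behind the calibration are represented
  here as material-point histories; converting published grip
  displacements to strain requires gauge lengths that are not part of the
  parameter set and is left to the user.
* Viscoelasticity is absent: an elastically loaded point does not relax at
  all, and after a plastic hold a substantial equilibrium stress always
  remains.
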