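# bonevpd

Material-point simulation of bone tissue with an orthotropic
visco-plasto-damage constitutive model, plus the octree-based assignment of
local orthotropic material axes from orientation point clouds.

The package is aimed at computational biomechanics: calibrating and probing
a bone constitutive law at a single material point (the homogeneous core of
a dumbbell or cylindrical specimen) before it is embedded in a finite
element model, and preparing CT-derived orientation data for such models.

## The model

The constitutive law couples four mechanisms, driven by the accumulated
plastic strain κ = ∫|ε̇ᵖ| dτ:

* **Damaged orthotropic elasticity** — σ = (1 − D(κ)) 𝕊 (ε − εᵖ), with 𝕊
  the orthotropic stiffness (transversely isotropic for the shipped
  cortical and trabecular presets) and D a scalar damage variable,
  D(κ) = 1 − e^(−k_p (κ − k₀)) for κ ≥ k₀, zero below the activation
  threshold k₀.
* **A Tsai-Wu-type yield surface** —
  Y(σ, κ) = √((σ − r(κ)A) : 𝔸 : (σ − r(κ)A)) − r(κ), an ellipsoidal
  surface in stress space whose centre A captures tension–compression
  asymmetry (kinematic term) and whose size follows the isotropic
  hardening function r(κ).  A and 𝔸 are built from the uniaxial yield
  strains ε₀⁺, ε₀⁻, the interaction coefficient ξ₀ and the fabric
  directions m₁, m₂, m₃.
* **Hardening with an optional softening branch** —
  r(κ) = 1 + (y_r − 1)(1 − e^(−s_h κ)) up to the onset κ = k_s, then
  r(k_s) e^(−s_s (κ − k_s)): the surface first expands towards y_r and
  then contracts, reproducing the post-peak stress decay seen in
  compression tests.
* **Perzyna viscoplasticity** — plastic flow ε̇ᵖ = γ ∇_σ Y with consistency
  parameter γ = (Y² + mY)/η, so positive overstress Y > 0 is admissible
  transiently and relaxes when the strain is held (stress relaxation).

Each time step is integrated by an elastic-predictor / plastic-corrector
return mapping: the nonlinear system [Ȳ; R; h] = 0 in the unknowns
(σ, γ, κ) is solved by Newton–Raphson with tolerances 10⁻⁶ on the full
residual and 10⁻⁸ on the generalized yield Ȳ = Y − φ(γ),
φ(γ) = −m/2 + √(m²/4 + ηγ) being the exact inverse of the Perzyna
relation.

The octree component indexes a point cloud of orientation triads
(positions + orthonormal material axes) and assigns to each query point the
triad of its nearest cloud point, with an exhaustive-scan oracle and
distance-evaluation counting to verify the pruned search.

## Worked example

A monotone uniaxial tension test on the cortical preset, 200 increments of
Δt = 0.01 s at strain rate 0.01/s:

```python
import numpy as np
from bonevpd import run_uniaxial
from bonevpd.fixtures import make_strain_program, preset_parameters

params = preset_parameters("cortical")
program = make_strain_program("ramp", amplitude=0.02, n_steps=200, rate=0.01)
record = run_uniaxial(program, params)

onset = next(i for i, r in enumerate(record.regime) if r == "plastic")
peak = record.stress[:, 0].argmax()
print(f"yield onset: eps = {record.strain[onset, 0]:.4f}, "
      f"sigma = {record.stress[onset, 0]:.1f} MPa")
print(f"peak stress: {record.stress[peak, 0]:.1f} MPa at eps = {record.strain[peak, 0]:.4f}")
print(f"end of test: sigma = {record.stress[-1, 0]:.1f} MPa, "
      f"kappa = {record.kappa[-1]:.4f}, damage D = {record.D[-1]:.3f}")
```

prints

```
yield onset: eps = 0.0019, sigma = 37.5 MPa
peak stress: 58.6 MPa at eps = 0.0093
end of test: sigma = 57.1 MPa, kappa = 0.0335, damage D = 0.154
```

Yielding starts one increment past the calibrated tensile yield strain
ε₀⁺ = 0.0018 (E₁·ε₀⁺ = 35.8 MPa); the stress peaks when κ crosses the
softening onset k_s = 0.01 and then decays while damage accumulates.

The same drivers are available from the shell:

```bash
bonevpd fixtures --kind program --shape ramp --amplitude 0.02 --out ramp.yaml
bonevpd uniaxial --params cortical --program ramp.yaml --out response.csv
bonevpd assign-axes --cloud cloud.csv --queries points.csv --out axes.csv
bonevpd fit-relaxation --in curve1.csv --in curve2.csv --out fits.json
```

## Layout

| module | contents |
| --- | --- |
| `bonevpd.parameters` | parameter dataclasses, YAML/JSON I/O, tissue presets |
| `bonevpd.constitutive` | elasticity, damage, hardening, yield surface, Perzyna functions |
| `bonevpd.return_mapping` | one-step elastic-predictor/plastic-corrector Newton solver |
| `bonevpd.drivers` | strain-path, mixed-control uniaxial and relaxation drivers |
| `bonevpd.relaxation` | power-law fits of relaxation curves, reduction averaging, yield-strain scaling |
| `bonevpd.octree` | orientation clouds, octree search, brute-force oracle, axes assignment |
| `bonevpd.fixtures` | deterministic generators for presets, programs, series and clouds |
| `bonevpd.cli` | `bonevpd` command-line entry point |

See `docs/methods.md` for the modeling assumptions, numerical choices and
known limitations.
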