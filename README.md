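# stentdeg

Crimping and in-vivo degradation simulator for poly(lactic acid)
bioresorbable vascular stents (BVS).

Biodegradable stents made of PLA scaffold a diseased coronary artery for
6–12 months and then resorb. How a particular lattice design crimps onto
its delivery balloon, deploys, and then loses molecular weight, volume and
radial strength over the following months is hard to measure in vivo;
`stentdeg` models it. The package is aimed at stent designers and
biomechanics researchers who want to compare parametric lattice designs —
four built-in families mirror commercial devices (Absorb, DESolve,
Igaki-Tamai, Fantom) — under a common, fully scripted protocol.

## Model

**Degradation.** Each material point carries the normalized number-average
molecular weight β(t) = Mn(t)/Mn(0), decaying by pseudo-first-order
hydrolysis, dβ/dt = −λβ, with a three-factor rate

    λ = λ₀ [ exp(bσ) + C_m + α_v − 1 ]

where σ is the local stress (stress lowers the activation energy of
hydrolysis, b ≡ B/RT), C_m the normalized concentration of acidic
hydrolysates (autocatalysis), and α_v = 1 + (ρ_dry/ρ_water)·α_m(t) the
volume swelling from water uptake. Hydrolysates obey Fick's second law
along the strut network with a strongly degradation-dependent diffusivity
φ = φ₀·e^{θ(1−β)}, a scission-tied source and first-order washout to
blood. A point dies when β < 0.01 or by a stochastic scission event with
hazard kλ; dead material is never removed — it keeps a water-like modulus
E_water. Strength and stiffness follow

    σ_y(t) = η σ_y0 e^{−φ∫λdt},   E(β) = (E_s0−E_water)·(e/(e−1))·(1−e^{−β}) + E_water

with η the fatigue knock-down for pulsatile blood pressure.

**Mechanics.** Struts are corotational Euler–Bernoulli beams with
fiber-resolved rectangular sections and elastic–perfectly-plastic fibers,
solved quasi-statically by Newton iteration. Crimping presses the lattice
against a shrinking rigid cylinder (penalty contact); expansion applies
trapezoidal balloon pressure against the artery, modelled as a closed-form
incompressible plane-strain Mooney–Rivlin thick-walled tube. The daily
degradation loop equilibrates the stent under the cycle-averaged blood
pressure (a three-Gaussian fit of the human pulse), maps element stresses
to material points, advances the kinetics, and records four indices: mean
molecular weight β̄, residual volume fraction v_r, mean stress σ̄, and
stent diameter D. A pilot five-indicator rank scoring (radial stiffness,
degradation slowness, residual volume, mean stress, final diameter)
compares designs.

## Worked example

```python
import stentdeg as sd

res = sd.run(
    sd.builtin_design("DESolve"),
    kinetics=sd.KineticParams(seed=1),
    vessel=sd.VesselSpec(),          # 3.0 mm lumen Mooney-Rivlin artery
    balloon=sd.BalloonProgram(),     # trapezoidal, 0.45 MPa peak
    waveform=sd.Waveform(),          # fitted human blood pressure
    n_days=180,
    segment_rings=3,
)
s = res.series
print(f"expansion ratio {s.expansion_ratio:.2f}")
print(f"day 180: beta={s.beta_mean[-1]:.3f}  v_r={s.v_r[-1]:.3f} "
      f"sigma={s.sigma_mean[-1]:.2f} MPa  D={s.D[-1]:.3f} mm")
```

prints (seed 1):

```
expansion ratio 1.00
day 180: beta=0.537  v_r=1.024  sigma=1.11 MPa  D=3.007 mm
```

i.e. the DESolve segment deploys to 3.0 mm, loses ~46 % of its molecular
weight over 180 days while its residual volume first swells (peaking near
day 22) and then declines as material points die, and it holds the lumen
diameter throughout.

The same protocols are available from the shell:

```sh
stentdeg build --design DESolve --out scratch/
stentdeg crimp --design DESolve --target 1.4 --out scratch/
stentdeg degrade --seed 1 --out scratch/run1/
stentdeg waveform --out scratch/
```

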