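# sprf — phase-resetting analysis of gamma synchronization in fast-spiking interneurons

Fast-spiking (FS) cortical interneurons are coupled by GABA_A synapses and
by gap junctions, and their synchronized firing underlies gamma oscillations
(30–80 Hz).  This package implements, as a tested in-silico pipeline, the
phase-resetting account of how those two connection types control
synchronization:

1. **Synthetic dynamic clamp.**  A conductance-based FS neuron (Na, Kv1,
   Kv3 and leak conductances in one compartment) is driven to steady gamma
   firing by a step of AMPA-like conductance, and perturbed by compound
   synaptic conductance events: a gap-junction input (constant conductance
   `g_e` whose reversal signal is a presynaptic action-potential waveform
   riding on a −70 mV baseline) plus a GABA_A input (difference-of-
   exponentials conductance, rise 0.5 ms, decay 7 ms, peak `g_i`, 3 ms
   latency).  Injected current follows Ohm's law, `I = g(t)(V − E_rev(t))`.
2. **The synaptic phase-resetting function (SPRF).**  For an input at phase
   `φ` of the firing cycle (phases in cycles, i.e. rad/2π), the phase shift
   `Δφ = 1 − (t_p + t_n)/T` is measured and fitted with the anchored
   piecewise-linear model

       Δφ(φ) = −β·φ            0 ≤ φ < φ_c      (delay, slope −β)
       Δφ(φ) =  α·(1 − φ)      φ_c ≤ φ < 1      (advance, slope −α)

   with the strength law `β = a·g_i`, `α = b·g_e`, `φ_c = c − d·g_e`.
   Fitting uses breakpoint profiling, Grubbs outlier rejection and a
   chi-square goodness-of-fit against the unperturbed phase variance.
3. **Entrainment prediction.**  The fitted SPRF defines a noisy
   stroboscopic circle map, `φ' = wrap(φ + Δφ(φ) + F/f + ξ)`,
   `ξ ~ N(0, σ²)`.  Deterministic 1:1 entrainment bands follow in closed
   form from corner-collision bifurcations
   (`r = f/F ∈ [1/(1+βφ_c), 1/(1−α(1−φ_c))]`); with noise, entrainment is
   classified from the discretized transfer operator: the second eigenvalue
   is real and positive for entrained relaxation, complex for drift.
   Inhibition extends the band below the natural rate F, electrical
   coupling above it, and noise shrinks the Arnol'd tongues.

## Worked example

```python
import numpy as np
from sprf import (FSModelParams, PhaseMapConfig, SPRFLaw,
                  run_perturbation_protocol, fit_piecewise,
                  deterministic_band, fixed_point)

# measure and fit the SPRF of the model cell at 40 Hz
params = FSModelParams()
curve = run_perturbation_protocol(params, F_target=40.0, g_e=0.75, g_i=1.5,
                                  phases=100)
fit, diag = fit_piecewise(curve)
print(f"beta = {fit.beta:.3f}, phi_c = {fit.phi_c:.2f}")

# entrainment band of the reference piecewise law
law = SPRFLaw(a=0.12, b=0.625, c=0.8, d=0.2)
band = deterministic_band(law, g_e=0.75, g_i=1.5)
print(f"1:1 band: f/F in [{band.r_lo:.4f}, {band.r_hi:.4f}]")

# locked phase of a 56 Hz cell entrained by a 50 Hz compound input
cfg = PhaseMapConfig(F_hz=56.0, f_hz=50.0, law=SPRFLaw(0.16, 0.69, 0.8, 0.2),
                     g_e_nS=0.75, g_i_nS=3.0)
print(f"locked phase: {fixed_point(cfg).phi:.2f} cycles")
```

prints

```
beta = 0.214, phi_c = 0.56
1:1 band: f/F in [0.8953, 1.1963]
locked phase: 0.25 cycles
```

The measured delay slope corresponds to `a ≈ 0.14 /nS` of inhibition; the
band means a cell with 0.75 nS electrical and 1.5 nS GABAergic coupling can
be entrained from ~10% below to ~20% above its natural rate; the locked
phase of 0.25 cycles means the entrained cell fires a quarter-cycle after
each stimulus.

A command-line interface exposes the three experiments:

```
sprf simulate --rate 40 --out out/          # steady firing of the cell
sprf sprf --out out/                        # SPRF grid + fits + law
sprf entrain --out out/                     # stroboscopic runs and S(f)
sprf tongue --out out/                      # entrainment maps and areas
```

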