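# Methods

This note documents the models, numerical procedures and design choices
behind the package, and what its tests do and do not establish.

## The conductance-based FS cell (`sprf.fs_model`)

A single electrical compartment with transient sodium (m³h), slow
low-threshold Kv1.3-like potassium (n₁⁴), fast high-threshold Kv3.1/3.2-like
potassium (n₃²) and static leak conductances:

    C dV/dt = −g_Na m³h (V−E_Na) − g_K1 n₁⁴ (V−E_K) − g_K3 n₃² (V−E_K)
              − g_L (V−E_L) − Σ g_inj(t)(V − E_inj(t))

Gate kinetics follow the FS-cell model of Erisir, Lau, Rudy & Leonard
(J Neurophysiol 82:2476, 1999); all rate coefficients are collected in one
table in `fs_model._rates`.  Units are mV, ms, nS, pA, pF throughout, so
`I = g(V−E)` needs no unit factors.

Three completions adapt that model to the conditions this generator must
emulate, each exposed as an explicit parameter:

* **Compartment size.**  Conductance densities are scaled to a 40 pF
  (≈4000 µm²) compartment, placing the resting input conductance near
  7 nS (~150 MΩ), in the range measured for FS cells.  This matters
  because the synaptic strengths studied (0.1–3 nS) must be perturbations,
  not dominant conductances.
* **`gate_rate_scale` (default 5).**  A Q10-style speed factor on all
  gating rates: the source kinetics were characterized near room
  temperature, while the phenomena emulated here occur at 31–35 °C.  It
  also keeps the spike afterhyperpolarization brief, so the interspike
  trajectory spends most of the cycle in the slow depolarizing approach
  rather than recovering from the AHP.
* **`kv1_rate_scale` (default 4) and `g_k1_nS` (default 12).**  The Kv1
  (D-type) current is the canonical mechanism of the abrupt ("type 2")
  onset of repetitive firing in FS cells.  With the published rate
  coefficients Kv1 is slow enough to act as an adaptation current, which
  *softens* the onset; the extra speed factor restores its restorative
  role.  The density is chosen so the onset is abrupt while 40 Hz firing
  retains enough margin above rheobase that a 1.5–2 nS shunting input
  delays spikes rather than deleting them.

The leak conductance (default 6 nS) is deliberately smaller than the
source-model value at this compartment size (10 nS), raising input
resistance toward measured FS values; it is a plain parameter.

With the defaults the model rests at −69.3 mV, is silent below ~0.53 nS of
step drive, then jumps to sustained regular firing whose rate rises very
steeply (~190 Hz/nS near onset versus ~47 Hz/nS in the gamma band — the
f–I curve is continuous but nearly vertical at onset), fires with CV < 0.01
throughout 15–80 Hz, and enters depolarization block above ~3 nS.

**Integration** is fixed-step exponential Euler for the gates and for V
(conductances held over one step), default dt = 0.01 ms.  The scheme is
unconditionally stable; halving dt moves spike times by < 0.05 ms over
300 ms.  Identical inputs give bit-identical trajectories, so protocol
runs are exactly reproducible.  The resting state is obtained by a 500 ms
unstimulated settling run (cached per parameter set).

**Spike detection** uses positive-going crossings of a threshold 10 mV
below the spike peak, with the peak estimated per trace from its first
suprathreshold excursion (making the rule invariant to voltage offsets),
and linear interpolation for sub-sample timing.

## Stimuli (`sprf.stimuli`)

* Drive: step conductance reversing at 0 mV, amplitude calibrated by
  bisection on the steady firing rate (with a long-run verification,
  since near-rheobase transients can mimic slow sustained rates).
* Gap junction: constant conductance `g_e`; its reversal signal is −70 mV
  except during a 10 ms action-potential waveform extracted from the
  model's own steady firing (edges cosine-tapered to exactly −70 mV).
  By default the gap conductance is connected for the whole simulation
  ("persistent" mode — a static electrical synapse onto a presynaptic cell
  held at −70 mV); an event-only mode is available for sensitivity checks.
  The persistent load is included when calibrating the drive.
* GABA_A: difference of exponentials (rise 0.5 ms, decay 7 ms) normalized
  so `g_i` is the **peak** conductance, delivered 3 ms after the gap event
  to model synaptic latency.  Event trains sum linearly.

**E_GABA.**  Events default to E_GABA = −55 mV, the value measured in FS
cells.  The conductance-based protocol, however, uses −65 mV
(`pipeline.MODEL_E_GABA_MV`): what defines GABAergic action in this system
is that inhibition is *shunting relative to the interspike trajectory* —
real FS cells ride a few mV above E_GABA between spikes.  The completed
model's interspike trajectory runs ~5 mV lower than real cells', so with
−55 mV the "inhibitory" input would be depolarizing for most of the cycle
and would advance, not delay.  Placing the model's E_GABA just below its
own trajectory restores the documented regime; the measured delay slope
then gives a ≈ 0.14–0.15 /nS, matching the experimentally reported range
(0.12–0.16 /nS) with no further adjustment.

## SPRF measurement (`sprf.pipeline`)

Phases are in cycles (rad/2π) everywhere; display conversions only.
Each perturbation runs in its own simulation from the identical settled
state: a calibration run yields the steady spike times and period T
(ISI CV must be < 0.05), the event is scheduled at phase φ of the cycle
after `settle_cycles` (default 5) steady cycles, and
`Δφ = 1 − (t_p + t_n)/T`.  Because the model is deterministic, isolation
between perturbations is exact (doubling `settle_cycles` changes nothing
beyond integration noise).  Default phase sampling is a uniform 100-point
grid; a seed switches to uniform-random phases.  Second-order resetting is
`Δφ₂ = 1 − ISI_following/T`.  The synchrony index is the phase order
parameter S = |mean exp(2πiφ)|, and the noise scale σ² is the variance of
normalized unperturbed ISIs.

## Fitting (`sprf.fit`)

The anchored two-segment model has three parameters (β, α, φ_c).  The
breakpoint is profiled over the midpoints between consecutive sample
phases (the exact profile set: SSE is piecewise constant in φ_c between
samples), with two refinements that matter in practice:

* candidates must leave ≥ 3 samples on each branch — otherwise noise
  profiling happily places 1–2 points on the advance branch near φ = 1,
  where the regressor (1−φ) is tiny, and inflates α several-fold;
* branch slopes are constrained to ≥ 0 (the model space), by clamping the
  through-origin least-squares slope — the constrained optimum for a
  quadratic objective.  Unconstrained estimates are kept in diagnostics.

Ties in SSE break toward the larger φ_c.  Grubbs' two-sided outlier test
(α = 0.05, at most 3 removals) is applied to the residuals, and the model
is refitted on the kept samples; removed points are reported, never
silently dropped.  An unanchored 5-parameter variant (intercepts on both
branches) is available behind `anchored=False` for sensitivity checks.
Goodness of fit: χ² = Σr²/σ² with dof = n_kept − 3, adequacy declared at
p ≥ 0.05.  The strength law is fitted by through-origin regressions of β
on g_i and α on g_e, and a straight line of φ_c on g_e.

Statistical reality check: at the experimentally observed noise level
(σ² = 0.021 cycles², i.e. sd ≈ 0.145 cycles) with 60 samples, per-branch
slope standard errors are ~30% of the slopes themselves, so single-curve
estimates scatter widely (the tests assert median-centering rather than
tight recovery); pooling across conditions, as the strength-law regression
does, is what produces stable parameters.

## Phase map and bifurcations (`sprf.phase_map`, `sprf.bifurcation`)

The stroboscopic map is `φ' = wrap(φ + Δφ(φ) + F/f + ξ)` with
ξ ~ N(0, σ²) per stimulus period (σ in cycles; no scaling with period).
The resetting is applied at the sampled phase before the free-running
advance; an after-advance variant exists behind `order="advance_first"`
and has the same entrained-frequency set (verified by test).  Phases at
φ_c take the advance-branch value.

Deterministic 1:1 entrainment requires Δφ(φ*) = 1 − F/f, solvable iff
1 − F/f lies in the SPRF's range [−βφ_c, α(1−φ_c)]; the band edges are
corner-collision bifurcations, and stability needs the branch slope
magnitude < 2.  Everything depends on frequencies only through r = f/F,
so tongues and areas are computed on the dimensionless ratio axis.

For σ > 0 the map's Markov operator is discretized as a column-stochastic
matrix (default 256 bins): each column is a wrapped Gaussian centered at
the deterministic image of the bin center, integrated over destination
bins, with wrap images covering ±4σ (error < 1e−7 for σ ≤ 0.3).
Entrainment is classified from the second-largest-modulus eigenvalue λ₂:
**real and positive** means entrained relaxation; complex means rotational
drift; real and *negative* means period-2 alternation near a p:q resonance
(e.g. at r ≈ 0.64 ≈ 16/25) and is classified as not 1:1-entrained — without
the sign requirement such resonances contaminate the tongue maps far from
the 1:1 band.  Modulus ties between a real eigenvalue and a complex pair
(tolerance 1e−9) resolve as drifting.  The leading eigenvector gives the
stationary phase density, whose first circular moment is the steady-state
synchrony; it agrees with 10⁵-step simulations of the map to |ΔS| < 0.01
and with 10⁶-iterate histograms to total variation < 0.02.

The stochastic classification boundary sits inward of the deterministic
corners by a few σ (measured ≈1.5σ at the lower corner, ≈3σ at the upper)
and converges to them as σ → 0.  Noise-shrinkage areas are counted on the
default plane g_e ∈ [0, 1.5] nS × r ∈ [0.6, 1.6] (60×100 grid, g_i = 1.5
nS): the entrained area at σ = 0.1 is ≈0.25 of the noise-free area, and
areas decrease monotonically along the σ ladder {0, 0.025, 0.05, 0.1}.

## What the synthetic data does and does not show

The generator is a deterministic point-neuron model: it emulates the
conductance-injection experiments' stimulus construction, timing
conventions and analysis chain exactly, and reproduces the qualitative
SPRF phenotype (early linear delay scaling with g_i, late advance scaling
with g_e, a crossover moving earlier with g_e, negligible second-order
resetting — measured ratio ≈ 0.04).  It does not capture: channel noise
(phase noise enters only abstractly through σ in the map), dendritic
filtering, or the full sharpness of the real cells' delay/advance corner —
the model's advance lobe is a smooth bump peaking near φ ≈ 0.8 rather than
a line falling from φ_c, so anchored two-segment fits of model-generated
curves under-estimate α at small g_e even though the measured advance
grows strictly with g_e.  Conclusions about real cells should rest on the
map/bifurcation layer (which consumes fitted parameters from any source,
including CSV tables of experimental samples), not on the biophysical
generator's fine structure.

## Problem sizes used by the test suite

Protocol runs use 100 perturbation phases per condition (a 500-phase
high-resolution sweep is available via `phases=500`); Monte-Carlo studies
use 100–200 replicates; operator grids use 256 bins (128 for the σ-ladder
area scan on a 40×50 grid); simulation cross-checks use 10⁵–10⁶ map
iterates.  These sizes keep the full suite to roughly a quarter hour on
one CPU while leaving every quantity's sampling error well inside the
asserted tolerances.
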