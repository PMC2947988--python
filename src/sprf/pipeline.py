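"""Perturbation protocol: from spike times to the synaptic phase-resetting
function (SPRF).

During steady periodic firing at rate F, an isolated compound synaptic
conductance event is delivered at a known phase of the cycle.  With t_p the
time from the preceding spike to the event, t_n the time from the event to
the next spike, and T the unperturbed period, the stimulus phase and the
phase shift are (in cycles, i.e. rad/2pi)

    phi_p = t_p / T,        dphi = 1 - (t_p + t_n) / T,

so dphi > 0 is a phase advance (next spike early) and dphi < 0 a delay.
The protocol isolates perturbations by separating them with several
unperturbed cycles; for the deterministic conductance-based cell each
perturbation is run from the identical settled state, so isolation is exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fs_model
from .fs_model import FSModelParams, SpikeTrain, detect_spikes, simulate
from .stimuli import APWaveform, ConductanceEvent, StimulusProgram, compound_event

logger = logging.getLogger(__name__)

#: GABA reversal used in the conductance-based protocol runs.  The defining
#: feature of GABA_A input onto FS cells is that it is shunting relative to
#: the interspike trajectory; the model's interspike orbit rides a few mV
#: lower than that of real FS cells, so its E_GABA is placed just below the
#: orbit to preserve that relationship (see docs/methods.md).
MODEL_E_GABA_MV = -65.0


@dataclass(frozen=True)
class SPRFSample:
    """One (phi, dphi) measurement with its raw timing quantities."""

    t_p_ms: float
    t_n_ms: float
    T_ms: float
    g_e_nS: float
    g_i_nS: float
    F_hz: float
    t_n2_ms: float = np.nan  # ISI following the perturbed one (2nd order)

    @property
    def phi(self) -> float:
        return self.t_p_ms / self.T_ms

    @property
    def dphi(self) -> float:
        return 1.0 - (self.t_p_ms + self.t_n_ms) / self.T_ms


@dataclass
class SPRFCurve:
    """SPRF samples for one (g_e, g_i, F) condition, plus fit results."""

    samples: list[SPRFSample]
    g_e_nS: float
    g_i_nS: float
    F_hz: float
    T_ms: float = np.nan
    meta: dict = field(default_factory=dict)
    fit: object = None          # PiecewiseSPRF once fitted
    diagnostics: object = None  # FitDiagnostics once fitted

    def __post_init__(self):
        for s in self.samples:
            if (s.g_e_nS, s.g_i_nS, s.F_hz) != (self.g_e_nS, self.g_i_nS,
                                                self.F_hz):
                raise ValueError("all samples must share one condition")

    @property
    def phi(self) -> np.ndarray:
        return np.array([s.phi for s in self.samples])

    @property
    def dphi(self) -> np.ndarray:
        return np.array([s.dphi for s in self.samples])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "phi_cycles": self.phi,
            "dphi_cycles": self.dphi,
            "tp_ms": [s.t_p_ms for s in self.samples],
            "tn_ms": [s.t_n_ms for s in self.samples],
            "T_ms": [s.T_ms for s in self.samples],
            "ge_nS": self.g_e_nS,
            "gi_nS": self.g_i_nS,
            "F_hz": self.F_hz,
        })


def compute_phase_shift(t_p: float, t_n: float, T: float) -> tuple[float, float]:
    """(phi_p, dphi) in cycles from the raw perturbation timings."""
    if T <= 0:
        raise ValueError("T must be > 0")
    if not (0 <= t_p < T):
        raise ValueError("require 0 <= t_p < T")
    if t_n <= 0:
        raise ValueError("t_n must be > 0")
    return t_p / T, 1.0 - (t_p + t_n) / T


def synchrony(phases) -> float:
    """Phase order parameter S: modulus of the mean unit phasor.

    1 when all phases coincide (mod 1), ~0 for phases spread uniformly
    around the circle.  Phases are in cycles.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("need at least one phase")
    return float(np.abs(np.mean(np.exp(2j * np.pi * phases))))


def unperturbed_phase_variance(train: SpikeTrain | np.ndarray) -> float:
    """Variance of normalized interspike intervals (cycles^2) from an
    unperturbed spike train; the noise scale sigma^2 used in chi-square
    goodness-of-fit tests and in the stochastic phase map."""
    times = train.times_ms if isinstance(train, SpikeTrain) else np.asarray(train)
    isis = np.diff(times)
    if isis.size < 20:
        raise ValueError("need at least 20 interspike intervals")
    return float(np.var(isis / isis.mean(), ddof=1))


def second_order_shift(curve: SPRFCurve) -> np.ndarray:
    """Per-sample second-order resetting dphi2 = 1 - ISI_following / T.

    The interval *after* the perturbed one should be back at the unperturbed
    period if the perturbation's effect is confined to the cycle in which it
    arrives (no second-order resetting).
    """
    out = []
    for s in curve.samples:
        if np.isnan(s.t_n2_ms):
            out.append(np.nan)
        else:
            out.append(1.0 - s.t_n2_ms / s.T_ms)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# protocol on the conductance-based cell

def _steady_run(params, drive, g_e, waveform, duration, dt, e_gaba):
    """Simulate drive + persistent gap baseline (no perturbation event)."""
    events = [ConductanceEvent("drive_step", 0.0, drive)]
    if g_e > 0:
        flat = APWaveform(np.array([0.0, 2 * dt]), np.array([-70.0, -70.0]))
        events.append(ConductanceEvent("gap", 5 * dt, g_e, waveform=flat))
    prog = StimulusProgram(events=events, duration_ms=duration, dt_ms=dt)
    trace = simulate(params, prog, dt=dt)
    return detect_spikes(trace)


def calibrate_drive(params, F_target, g_e=0.0, waveform=None, dt=0.01,
                    tolerance=0.3, duration=1200.0, discard=400.0,
                    e_gaba=MODEL_E_GABA_MV):
    """Drive amplitude giving steady rate F_target with the persistent
    gap-junction baseline conductance connected (it loads the membrane and
    must be present during calibration)."""
    if g_e == 0:
        return fs_model.find_drive_for_rate(params, F_target, max(tolerance, 0.3), dt=dt)
    lo, hi = 0.0, 8.0
    best = None
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        train = _steady_run(params, mid, g_e, waveform, duration, dt, e_gaba)
        t = train.times_ms[train.times_ms > discard]
        r = 0.0 if t.size < 3 else 1000.0 / np.diff(t).mean()
        if r < F_target:
            lo = mid
        else:
            hi = mid
            best = (mid, r)
        if best and abs(best[1] - F_target) < tolerance:
            break
    if best is None or abs(best[1] - F_target) > max(tolerance, 0.5):
        raise ValueError(f"could not calibrate drive for {F_target} Hz "
                         f"with g_e={g_e} nS connected")
    return best[0]


def run_perturbation_protocol(
    params: FSModelParams,
    F_target: float,
    g_e: float,
    g_i: float,
    phases: np.ndarray | int = 100,
    settle_cycles: int = 5,
    seed: int | None = None,
    dt: float = 0.01,
    drive: float | None = None,
    waveform: APWaveform | None = None,
    e_gaba: float = MODEL_E_GABA_MV,
    isi_cv_max: float = 0.05,
) -> SPRFCurve:
    """Measure the SPRF of the conductance-based cell at one condition.

    Each perturbation is delivered in its own deterministic run from the
    identical settled state: a calibration run (drive + persistent gap
    baseline, no event) yields the steady spike times and period T; the
    event is then scheduled at phase phi of the cycle following
    ``settle_cycles`` steady cycles.  ``phases`` is either an explicit
    array of phases in [0, 1) or a count for a uniform grid; passing a
    ``seed`` replaces the grid with uniform-random phases.
    """
    if isinstance(phases, (int, np.integer)):
        n = int(phases)
        if seed is not None:
            rng = np.random.default_rng(seed)
            phases = rng.uniform(0.0, 1.0, n)
        else:
            phases = (np.arange(n) + 0.5) / n
    phases = np.asarray(phases, dtype=float)
    if np.any((phases < 0) | (phases >= 1)):
        raise ValueError("phases must lie in [0, 1)")

    if waveform is None and g_e > 0:
        waveform = fs_model.generate_ap_waveform(params, dt=dt)
    if drive is None:
        drive = calibrate_drive(params, F_target, g_e, waveform, dt=dt,
                                e_gaba=e_gaba)

    # calibration run: steady spikes with the same persistent load
    T_nom = 1000.0 / F_target
    settle_ms = 400.0
    calib_dur = settle_ms + (settle_cycles + 6) * T_nom
    train = _steady_run(params, drive, g_e, waveform, calib_dur, dt, e_gaba)
    steady = train.times_ms[train.times_ms > settle_ms]
    if steady.size < settle_cycles + 3:
        raise RuntimeError("cell not firing steadily during calibration")
    isis = np.diff(steady)
    if isis.std() / isis.mean() > isi_cv_max:
        raise RuntimeError(
            f"firing not periodic before perturbation (ISI CV = "
            f"{isis.std() / isis.mean():.3f})")
    T = float(isis.mean())
    ref = steady[settle_cycles]

    samples = []
    for phi in phases:
        t_ev = ref + phi * T
        events = [ConductanceEvent("drive_step", 0.0, drive)]
        events += compound_event(g_e, g_i, t_ev, waveform, e_gaba=e_gaba)
        prog = StimulusProgram(events=events, duration_ms=t_ev + 6 * T,
                               dt_ms=dt)
        trace = simulate(params, prog, dt=dt)
        spikes = detect_spikes(trace).times_ms
        prev = spikes[spikes <= t_ev]
        nxt = spikes[spikes > t_ev]
        if prev.size == 0 or nxt.size == 0:
            logger.warning("no bracketing spikes for phi=%.3f; skipped", phi)
            continue
        t_p = t_ev - prev[-1]
        t_n = nxt[0] - t_ev
        t_n2 = (nxt[1] - nxt[0]) if nxt.size > 1 else np.nan
        samples.append(SPRFSample(t_p, t_n, T, g_e, g_i, F_target,
                                  t_n2_ms=t_n2))

    return SPRFCurve(samples=samples, g_e_nS=g_e, g_i_nS=g_i, F_hz=F_target,
                     T_ms=T,
                     meta={"drive_nS": drive, "settle_cycles": settle_cycles,
                           "seed": seed, "dt_ms": dt, "e_gaba_mV": e_gaba})


def curve_from_map(law, g_e, g_i, phases, noise_sd=0.0, seed=None,
                   F_hz=40.0) -> SPRFCurve:
    """Synthetic SPRF samples drawn from a piecewise-linear law (plus
    optional Gaussian phase noise) expressed as an SPRFCurve, for pipeline
    testing and calibration studies.  Map-generated data is memoryless, so
    its second-order resetting is exactly zero (t_n2 = T)."""
    from .fit import SPRFLaw, PiecewiseSPRF  # local import to avoid cycle

    if isinstance(law, SPRFLaw):
        model = law.evaluate(g_e, g_i)
    else:
        model = law
    phases = np.asarray(phases, dtype=float)
    rng = np.random.default_rng(seed)
    dphi = model(phases)
    if noise_sd > 0:
        dphi = dphi + rng.normal(0.0, noise_sd, phases.size)
    T = 1000.0 / F_hz
    samples = [
        SPRFSample(t_p_ms=phi * T, t_n_ms=T * (1.0 - phi - d), T_ms=T,
                   g_e_nS=g_e, g_i_nS=g_i, F_hz=F_hz, t_n2_ms=T)
        for phi, d in zip(phases, dphi)
    ]
    return SPRFCurve(samples=samples, g_e_nS=g_e, g_i_nS=g_i, F_hz=F_hz,
                     T_ms=T, meta={"seed": seed, "noise_sd": noise_sd,
                                   "source": "map"})
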