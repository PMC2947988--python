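"""Conductance-injection stimulus programs.

A stimulus program is a set of timed conductance events delivered to the
simulated cell through Ohm's law, ``I = g(t) * (V - E_rev(t))``.  Three kinds
of source are supported:

* ``drive_step`` — a step of AMPA-like excitatory conductance reversing at
  0 mV, used to elicit steady repetitive firing.
* ``gap`` — an electrical synapse: a constant conductance ``g_e`` whose
  reversal-potential signal is the membrane-potential trajectory of a
  presynaptic cell, held at -70 mV except for an action-potential waveform
  excursion at each event time (the "voltage-source" approximation).
* ``gaba`` — a GABA_A synapse: a difference-of-exponentials conductance
  transient (rise 0.5 ms, decay 7 ms) reversing at E_GABA (default -55 mV),
  delivered 3 ms after the presynaptic action-potential onset to model
  synaptic latency.

Programs compile to per-source sample series on the integration grid; the
series of a train is the shifted sum of single-event series.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

GAP_BASELINE_MV = -70.0
E_GABA_DEFAULT_MV = -55.0
E_DRIVE_MV = 0.0
GABA_TAU_RISE_MS = 0.5
GABA_TAU_DECAY_MS = 7.0
GABA_LATENCY_MS = 3.0


@dataclass(frozen=True)
class APWaveform:
    """A presynaptic action-potential voltage waveform (the E_rev signal
    of the gap-junction source), sampled uniformly, endpoints at -70 mV."""

    t_ms: np.ndarray
    v_mV: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t_ms, dtype=float)
        v = np.asarray(self.v_mV, dtype=float)
        if t.shape != v.shape or t.ndim != 1 or t.size < 2:
            raise ValueError("waveform requires matching 1-d time/voltage arrays")
        object.__setattr__(self, "t_ms", t)
        object.__setattr__(self, "v_mV", v)

    @property
    def duration_ms(self) -> float:
        return float(self.t_ms[-1] - self.t_ms[0])

    def resample(self, dt: float) -> np.ndarray:
        n = int(round(self.duration_ms / dt)) + 1
        tq = self.t_ms[0] + dt * np.arange(n)
        return np.interp(tq, self.t_ms, self.v_mV)


@dataclass(frozen=True)
class ConductanceEvent:
    """One timed conductance event.

    ``amplitude_nS`` is g_e for gap events, the peak conductance g_i for
    GABA events, and the step amplitude for drive steps.  ``offset_ms``
    (drive steps only) ends the step; ``None`` holds it to the end of the
    program.
    """

    kind: str  # "gap" | "gaba" | "drive_step"
    onset_ms: float
    amplitude_nS: float
    e_rev_mV: float | None = None          # fixed reversal (gaba / drive)
    waveform: APWaveform | None = None     # E_rev signal (gap)
    tau_rise_ms: float = GABA_TAU_RISE_MS
    tau_decay_ms: float = GABA_TAU_DECAY_MS
    latency_ms: float = GABA_LATENCY_MS
    offset_ms: float | None = None

    def __post_init__(self):
        if self.kind not in ("gap", "gaba", "drive_step"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.amplitude_nS < 0:
            raise ValueError("negative conductance amplitude")
        if self.kind == "gaba" and not (self.tau_decay_ms > self.tau_rise_ms > 0):
            raise ValueError("require tau_decay > tau_rise > 0")


def gaba_kernel(
    g_i: float,
    tau_rise: float = GABA_TAU_RISE_MS,
    tau_decay: float = GABA_TAU_DECAY_MS,
    dt: float = 0.01,
    window: float | None = None,
) -> np.ndarray:
    """Difference-of-exponentials GABA_A conductance transient.

    Normalized so that the peak equals ``g_i`` exactly (g_i is the peak
    conductance of the event).  Returns samples starting at the event onset.
    """
    if g_i < 0:
        raise ValueError("g_i must be >= 0")
    if not tau_decay > tau_rise > 0:
        raise ValueError("require tau_decay > tau_rise > 0")
    if window is None:
        window = 8.0 * tau_decay
    n = int(round(window / dt)) + 1
    t = dt * np.arange(n)
    shape = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    # closed-form peak of the difference of exponentials
    t_peak = gaba_peak_time(tau_rise, tau_decay)
    peak = math.exp(-t_peak / tau_decay) - math.exp(-t_peak / tau_rise)
    return g_i * shape / peak


def gaba_peak_time(tau_rise: float = GABA_TAU_RISE_MS,
                   tau_decay: float = GABA_TAU_DECAY_MS) -> float:
    """Time-to-peak of the difference-of-exponentials kernel."""
    return tau_rise * tau_decay / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)


def compound_event(
    g_e: float,
    g_i: float,
    t0: float,
    ap_waveform: APWaveform | None = None,
    e_gaba: float = E_GABA_DEFAULT_MV,
    latency: float = GABA_LATENCY_MS,
) -> list[ConductanceEvent]:
    """A compound electrical/GABAergic synaptic event.

    The gap component starts at ``t0`` (the presynaptic AP onset); the GABA
    component follows after the synaptic latency (default 3 ms).  Either
    component may have zero amplitude.
    """
    if g_e > 0 and ap_waveform is None:
        raise ValueError("gap component requires an AP waveform")
    events = [
        ConductanceEvent("gap", t0, g_e, waveform=ap_waveform),
        ConductanceEvent("gaba", t0 + latency, g_i, e_rev_mV=e_gaba,
                         latency_ms=latency),
    ]
    return events


@dataclass
class StimulusProgram:
    """An ordered list of conductance events plus compilation parameters.

    ``gap_mode`` selects whether the gap-junction conductance is connected
    for the whole simulation ("persistent", the default — a static electrical
    synapse onto a presynaptic cell held at -70 mV) or only during the AP
    waveform window ("event").
    """

    events: list[ConductanceEvent] = field(default_factory=list)
    duration_ms: float = 0.0
    dt_ms: float = 0.01
    gap_mode: str = "persistent"

    def __post_init__(self):
        if self.gap_mode not in ("persistent", "event"):
            raise ValueError("gap_mode must be 'persistent' or 'event'")
        self.events = sorted(self.events, key=lambda e: e.onset_ms)

    def add(self, event_or_list) -> "StimulusProgram":
        if isinstance(event_or_list, ConductanceEvent):
            self.events.append(event_or_list)
        else:
            self.events.extend(event_or_list)
        self.events.sort(key=lambda e: e.onset_ms)
        return self

    # -- compilation -------------------------------------------------------

    def compile(self, duration_ms: float | None = None, dt: float | None = None):
        """Render the program to per-source sample series.

        Returns a dict with arrays ``g_drive``, ``g_gap``, ``e_gap``,
        ``g_gaba`` (length n+1 covering t = 0..duration) and scalars
        ``e_drive``, ``e_gaba``.
        """
        duration = self.duration_ms if duration_ms is None else duration_ms
        dt = self.dt_ms if dt is None else dt
        if duration <= 0 or dt <= 0:
            raise ValueError("duration and dt must be positive")
        n = int(round(duration / dt)) + 1
        g_drive = np.zeros(n)
        g_gap = np.zeros(n)
        e_gap = np.full(n, GAP_BASELINE_MV)
        g_gaba = np.zeros(n)
        e_gaba = E_GABA_DEFAULT_MV

        gap_amp = None
        gap_windows: list[tuple[int, int]] = []
        for ev in self.events:
            if not (0 <= ev.onset_ms <= duration):
                raise ValueError(
                    f"event onset {ev.onset_ms} ms outside [0, {duration}] ms")
            i0 = int(round(ev.onset_ms / dt))
            if ev.kind == "drive_step":
                i1 = n if ev.offset_ms is None else min(n, int(round(ev.offset_ms / dt)))
                g_drive[i0:i1] += ev.amplitude_nS
            elif ev.kind == "gaba":
                e_gaba = E_GABA_DEFAULT_MV if ev.e_rev_mV is None else ev.e_rev_mV
                kern = gaba_kernel(ev.amplitude_nS, ev.tau_rise_ms,
                                   ev.tau_decay_ms, dt)
                i1 = min(n, i0 + kern.size)
                g_gaba[i0:i1] += kern[: i1 - i0]
            elif ev.kind == "gap":
                if ev.amplitude_nS == 0:
                    continue
                if gap_amp is None:
                    gap_amp = ev.amplitude_nS
                elif not math.isclose(gap_amp, ev.amplitude_nS):
                    raise ValueError(
                        "all gap events in one program must share g_e "
                        "(a single electrical synapse)")
                if ev.waveform is None:
                    raise ValueError("gap event without AP waveform")
                wav = ev.waveform.resample(dt)
                i1 = min(n, i0 + wav.size)
                if gap_windows and i0 < gap_windows[-1][1]:
                    logger.warning(
                        "gap waveform at %.3f ms truncates the previous one",
                        ev.onset_ms)
                e_gap[i0:i1] = wav[: i1 - i0]
                gap_windows.append((i0, i1))

        if gap_amp is not None:
            if self.gap_mode == "persistent":
                g_gap[:] = gap_amp
            else:
                for i0, i1 in gap_windows:
                    g_gap[i0:i1] = gap_amp

        for name, series in (("g_drive", g_drive), ("g_gap", g_gap),
                             ("g_gaba", g_gaba)):
            if np.any(series < 0):
                raise ValueError(f"negative conductance in {name} series")
        return {
            "g_drive": g_drive, "e_drive": E_DRIVE_MV,
            "g_gap": g_gap, "e_gap": e_gap,
            "g_gaba": g_gaba, "e_gaba": e_gaba,
            "dt": dt, "duration": duration,
        }


def periodic_train(
    event_template: list[ConductanceEvent],
    f: float,
    n_events: int,
    t_start: float = 0.0,
    duration_ms: float | None = None,
    dt: float = 0.01,
    gap_mode: str = "persistent",
) -> StimulusProgram:
    """Repeat a (compound) event template at frequency ``f`` Hz.

    Event copies are placed at exact multiples of the period; overlapping
    GABA tails from successive events sum linearly.
    """
    if f <= 0:
        raise ValueError("f must be > 0")
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    period = 1000.0 / f
    events: list[ConductanceEvent] = []
    for k in range(n_events):
        shift = t_start + k * period
        for ev in event_template:
            events.append(replace(ev, onset_ms=ev.onset_ms + shift))
    if duration_ms is None:
        duration_ms = t_start + n_events * period + 50.0
    return StimulusProgram(events=events, duration_ms=duration_ms, dt_ms=dt,
                           gap_mode=gap_mode)
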