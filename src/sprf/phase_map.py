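"""Noisy stroboscopic circle map of the phase under periodic stimulation.

The phase phi of a cell firing at natural rate F, observed at the arrival
times of periodic stimuli at rate f, evolves per stimulus as

    phi_{n+1} = wrap( phi_n + dphi(phi_n) + F/f + xi_n ),   xi ~ N(0, sigma^2)

where dphi is the piecewise-linear SPRF evaluated through the synaptic-
strength law, F/f is the free-running advance per stimulus period
(detuning), and xi is Gaussian phase noise in cycles per stimulus.  With
the stimulus off, dphi = 0 and the phase drifts in a sawtooth.  A stable
fixed point of the noise-free map is 1:1 entrainment; the fixed-point
condition is dphi(phi*) = 1 - F/f, so entrainment below the natural rate
(F > f) requires delays (inhibition) and entrainment above it (F < f)
requires advances (electrical coupling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from numba import njit

from .fit import PiecewiseSPRF, SPRFLaw


@dataclass(frozen=True)
class PhaseMapConfig:
    """Stochastic circle-map configuration.

    ``order`` selects whether the SPRF resetting is evaluated at the phase
    at which the stimulus arrives ("perturb_first", default) or after the
    free-running advance ("advance_first"); the two variants have the same
    set of entrained frequencies, only transient orbits differ.
    """

    F_hz: float
    f_hz: float
    law: SPRFLaw
    g_e_nS: float
    g_i_nS: float
    sigma: float = 0.0
    seed: int | None = None
    order: str = "perturb_first"

    def __post_init__(self):
        if self.F_hz <= 0 or self.f_hz <= 0:
            raise ValueError("F and f must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.order not in ("perturb_first", "advance_first"):
            raise ValueError("order must be 'perturb_first' or 'advance_first'")

    @property
    def sprf(self) -> PiecewiseSPRF:
        return self.law.evaluate(self.g_e_nS, self.g_i_nS)

    @property
    def detuning(self) -> float:
        """Free-running phase advance per stimulus period, F/f (cycles)."""
        return self.F_hz / self.f_hz


@dataclass
class StroboscopicSeries:
    phases: np.ndarray
    stimulus_on: np.ndarray
    config: PhaseMapConfig

    def __post_init__(self):
        if np.any((self.phases < 0) | (self.phases >= 1)):
            raise ValueError("phases must lie in [0, 1)")


class FixedPoint(NamedTuple):
    phi: float
    stable: bool
    branch: str  # "delay" | "advance"


@njit(cache=False)
def _iterate(phi0, n, alpha, beta, phi_c, ratio, sigma, seed, stim_on,
             advance_first):
    out = np.empty(n + 1)
    out[0] = phi0
    if seed >= 0:
        np.random.seed(seed)
    phi = phi0
    for i in range(n):
        xi = sigma * np.random.standard_normal() if sigma > 0 else 0.0
        if stim_on:
            if advance_first:
                psi = (phi + ratio) % 1.0
                d = -beta * psi if psi < phi_c else alpha * (1.0 - psi)
                phi = (psi + d + xi) % 1.0
            else:
                d = -beta * phi if phi < phi_c else alpha * (1.0 - phi)
                phi = (phi + d + ratio + xi) % 1.0
        else:
            phi = (phi + ratio + xi) % 1.0
        out[i + 1] = phi
    return out


def map_step(phi: float, config: PhaseMapConfig, rng=None) -> float:
    """One application of the stroboscopic map (stimulus on)."""
    m = config.sprf
    xi = 0.0
    if config.sigma > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        xi = config.sigma * rng.standard_normal()
    if config.order == "advance_first":
        psi = (phi + config.detuning) % 1.0
        return (psi + m(psi) + xi) % 1.0
    return (phi + m(phi) + config.detuning + xi) % 1.0


def deterministic_image(phi, config: PhaseMapConfig):
    """Unwrapped noise-free image of phase(s) phi (perturb-first order)."""
    m = config.sprf
    phi = np.asarray(phi, dtype=float)
    return phi + m(phi) + config.detuning


def fixed_point(config: PhaseMapConfig) -> FixedPoint | None:
    """Closed-form 1:1 entrained fixed point of the noise-free map.

    Solves dphi(phi*) = 1 - F/f on each branch: the delay branch gives
    phi* = (F/f - 1)/beta on [0, phi_c); the advance branch gives
    phi* = 1 - (1 - F/f)/alpha on [phi_c, 1).  Stability requires the
    branch slope magnitude < 2 (map derivative 1 - beta or 1 - alpha in
    (-1, 1))."""
    if config.sigma != 0:
        raise ValueError("fixed points are defined for the sigma = 0 map")
    m = config.sprf
    target = 1.0 - config.detuning  # required dphi
    # delay branch: -beta phi* = target
    if target <= 0:
        if target == 0:
            # zero detuning: the delay-branch anchor phi* = 0
            return FixedPoint(0.0, 0 < m.beta < 2, "delay")
        if m.beta > 0:
            phi = -target / m.beta
            if 0 <= phi < m.phi_c:
                return FixedPoint(float(phi), abs(1 - m.beta) < 1, "delay")
    else:
        if m.alpha > 0:
            phi = 1.0 - target / m.alpha
            if m.phi_c <= phi < 1:
                return FixedPoint(float(phi), abs(1 - m.alpha) < 1, "advance")
    return None


def stroboscopic_run(config: PhaseMapConfig, n_pre: int, n_on: int,
                     n_post: int, phi0: float = 0.0) -> StroboscopicSeries:
    """Phase at successive stimulus times: pre/post segments with the
    stimulus off (pure detuning drift plus noise) and an on-segment with
    the full map — the stroboscopic picture of an entrainment episode."""
    seed = -1 if config.seed is None else int(config.seed)
    adv = config.order == "advance_first"
    m = config.sprf
    segs = []
    on_mask = []
    phi = phi0
    for n, on, s in ((n_pre, False, seed), (n_on, True, seed + 1 if seed >= 0 else -1),
                     (n_post, False, seed + 2 if seed >= 0 else -1)):
        if n == 0:
            continue
        seg = _iterate(phi, n, m.alpha, m.beta, m.phi_c, config.detuning,
                       config.sigma, s, on, adv)
        phi = seg[-1]
        segs.append(seg[1:] if segs else seg)
        on_mask.append(np.full(segs[-1].size, on))
    return StroboscopicSeries(phases=np.concatenate(segs),
                              stimulus_on=np.concatenate(on_mask),
                              config=config)


def iterate_phases(config: PhaseMapConfig, n: int, phi0: float = 0.0,
                   discard: int = 0) -> np.ndarray:
    """Iterate the (noisy) map n steps and return the phases after an
    optional burn-in."""
    seed = -1 if config.seed is None else int(config.seed)
    m = config.sprf
    out = _iterate(phi0, n, m.alpha, m.beta, m.phi_c, config.detuning,
                   config.sigma, seed, True,
                   config.order == "advance_first")
    return out[discard:]


def synchrony_vs_frequency(config: PhaseMapConfig, f_grid, n_steps: int = 2000,
                           n_discard: int = 200, seed: int | None = None,
                           phi0: float = 0.0):
    """Synchrony S of the simulated noisy map across stimulus frequencies.

    Returns (f_grid, S) where S is the phase order parameter of the
    post-burn-in stroboscopic phases at each f."""
    if n_discard < 100:
        raise ValueError("burn-in must be >= 100 steps")
    from .pipeline import synchrony

    f_grid = np.asarray(f_grid, dtype=float)
    if seed is None:
        seed = config.seed
    S = np.empty(f_grid.size)
    for i, f in enumerate(f_grid):
        cfg = replace(config, f_hz=float(f),
                      seed=None if seed is None else int(seed) + i)
        phases = iterate_phases(cfg, n_steps, phi0=phi0, discard=n_discard)
        S[i] = synchrony(phases)
    return f_grid, S


def steady_state_synchrony(config: PhaseMapConfig, n_bins: int = 256) -> float:
    """Synchrony of the stationary phase distribution of the noisy map,
    computed from the leading eigenvector of the discretized transfer
    operator (first circular moment of the invariant density)."""
    if config.sigma <= 0:
        raise ValueError("steady-state synchrony needs sigma > 0; use "
                         "fixed_point for the deterministic map")
    from .bifurcation import build_transition_matrix

    tm = build_transition_matrix(config, n_bins)
    rho = tm.stationary_distribution()
    return float(np.abs(np.sum(rho * np.exp(2j * np.pi * tm.bin_centers))))
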