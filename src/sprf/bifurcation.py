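"""Entrainment bands of the phase map: corner-collision bifurcations,
Arnol'd tongues, and stochastic bifurcation via the transfer operator.

Deterministic case (sigma = 0): the 1:1 entrained fixed point exists while
1 - F/f lies in the range of the SPRF over the cycle, [-beta*phi_c,
alpha*(1-phi_c)]; it disappears when the fixed point collides with the
breakpoint or a branch end (a corner-collision bifurcation, not a smooth
tangency).  In the frequency ratio r = f/F the band is

    r_lo = 1 / (1 + beta*phi_c),   r_hi = 1 / (1 - alpha*(1-phi_c)),

so inhibition (beta > 0) extends the band below the natural rate and
electrical coupling (alpha > 0) above it.

Stochastic case (sigma > 0): the map becomes a Markov operator on the
circle, discretized as a column-stochastic transition matrix with
wrapped-Gaussian transition kernels.  Entrainment is classified by the
second eigenvalue: real (entrained relaxation toward a localized
stationary density) versus complex (rotation-dominated drift).  As
sigma -> 0 this boundary converges to the deterministic corner
frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .fit import SPRFLaw
from .phase_map import PhaseMapConfig, deterministic_image

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Band:
    """Deterministic 1:1 entrainment band in r = f/F."""

    r_lo: float
    r_hi: float
    alpha: float
    beta: float
    phi_c: float

    def contains(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        out = (r >= self.r_lo) & (r <= self.r_hi)
        return out if out.ndim else bool(out)

    @property
    def width(self) -> float:
        return self.r_hi - self.r_lo


def deterministic_band(law: SPRFLaw, g_e: float, g_i: float) -> Band:
    """Closed-form 1:1 band from the corner-collision conditions."""
    m = law.evaluate(g_e, g_i)
    r_lo = 1.0 / (1.0 + m.beta * m.phi_c)
    denom = 1.0 - m.alpha * (1.0 - m.phi_c)
    if denom <= 0:
        logger.warning("advance range >= 1 cycle: upper band edge unbounded")
        r_hi = np.inf
    else:
        r_hi = 1.0 / denom
    return Band(r_lo=r_lo, r_hi=r_hi, alpha=m.alpha, beta=m.beta,
                phi_c=m.phi_c)


@dataclass
class TransitionMatrix:
    """Column-stochastic discretization of the phase map's Markov operator.

    ``matrix[i, j]`` is the probability of moving from bin j to bin i in
    one stimulus period."""

    matrix: np.ndarray
    bin_centers: np.ndarray
    config: PhaseMapConfig

    def __post_init__(self):
        col = self.matrix.sum(axis=0)
        if np.any(np.abs(col - 1.0) > 1e-12):
            raise ValueError("columns must sum to 1")
        if np.any(self.matrix < 0):
            raise ValueError("entries must be >= 0")

    @property
    def n_bins(self) -> int:
        return self.bin_centers.size

    def eigenvalues(self, k: int | None = None) -> np.ndarray:
        """Eigenvalues sorted by modulus, descending."""
        ev = np.linalg.eigvals(self.matrix)
        ev = ev[np.argsort(-np.abs(ev))]
        return ev if k is None else ev[:k]

    def stationary_distribution(self) -> np.ndarray:
        """Invariant phase density (leading eigenvector, normalized)."""
        ev, vec = np.linalg.eig(self.matrix)
        i = int(np.argmax(ev.real - 1e6 * np.abs(ev.imag)))
        rho = np.real(vec[:, i])
        if rho.sum() < 0:
            rho = -rho
        rho = np.clip(rho, 0.0, None)
        return rho / rho.sum()


def build_transition_matrix(config: PhaseMapConfig,
                            n_bins: int = 256) -> TransitionMatrix:
    """Discretize the noisy map as a transition matrix.

    Column j is the wrapped Gaussian (sd sigma, cycles) centered at the
    deterministic image of bin center j, integrated over destination bins;
    wrap images are summed over +-4 sigma."""
    if config.sigma <= 0:
        raise ValueError("sigma must be > 0 (use deterministic_band)")
    if n_bins < 128:
        raise ValueError("n_bins must be >= 128")
    centers = (np.arange(n_bins) + 0.5) / n_bins
    edges = np.arange(n_bins + 1) / n_bins
    y = deterministic_image(centers, config)  # unwrapped images, shape (n,)
    sig = config.sigma
    k_lo = int(np.floor(y.min() - 4.0 * sig))
    k_hi = int(np.ceil(y.max() + 4.0 * sig))
    M = np.zeros((n_bins, n_bins))
    for k in range(k_lo, k_hi + 1):
        z = (edges[:, None] + k - y[None, :]) / sig
        cdf = ndtr(z)
        M += cdf[1:, :] - cdf[:-1, :]
    M /= M.sum(axis=0, keepdims=True)
    return TransitionMatrix(matrix=M, bin_centers=centers, config=config)


def stochastic_classify(tm: TransitionMatrix, imag_tol: float = 1e-8,
                        tie_tol: float = 1e-9) -> tuple[str, complex]:
    """Entrained vs drifting from the second eigenvalue of the operator.

    The leading eigenvalue is 1; the second-largest-modulus eigenvalue
    lambda_2 is real and positive for entrained (relaxational) dynamics.
    A complex lambda_2 signals rotation-dominated drift; a negative real
    lambda_2 signals period-2 alternation (a p:q resonance, not 1:1
    entrainment).  A tie in modulus between a real eigenvalue and a
    complex pair is resolved as drifting."""
    ev = tm.eigenvalues()
    if abs(abs(ev[0]) - 1.0) > 1e-8:
        raise RuntimeError("leading eigenvalue is not 1")
    rest = ev[1:]
    lam2 = rest[0]
    group = rest[np.abs(np.abs(rest) - abs(lam2)) <= tie_tol]
    is_real = np.abs(group.imag) <= imag_tol * np.maximum(1.0, np.abs(group))
    label = ("entrained"
             if bool(np.all(is_real)) and bool(np.all(group.real > 0))
             else "drifting")
    if lam2.imag < 0:
        lam2 = np.conj(lam2)
    return label, complex(lam2)


@dataclass
class Tongue:
    """Boolean 1:1 entrainment grid over (synaptic strength, f/F)."""

    axis_name: str            # "g_e" or "g_i"
    axis_values: np.ndarray
    r_values: np.ndarray
    entrained: np.ndarray     # shape (len(axis_values), len(r_values))
    sigma: float
    fixed: dict
    law: SPRFLaw
    n_bins: int = 256

    @property
    def cell_area(self) -> float:
        da = float(np.mean(np.diff(self.axis_values)))
        dr = float(np.mean(np.diff(self.r_values)))
        return da * dr

    @property
    def area(self) -> float:
        """(count of entrained cells) x cell area, exactly."""
        return int(self.entrained.sum()) * self.cell_area

    def boundary(self, i: int) -> tuple[float, float] | None:
        """(r_lo, r_hi) of the entrained run in axis row i, or None."""
        row = np.flatnonzero(self.entrained[i])
        if row.size == 0:
            return None
        return float(self.r_values[row[0]]), float(self.r_values[row[-1]])


def tongue(law: SPRFLaw, axis_name: str, axis_values, r_values,
           sigma: float = 0.0, fixed: dict | None = None,
           n_bins: int = 256, F_hz: float = 40.0) -> Tongue:
    """Classify 1:1 entrainment over a (strength, frequency-ratio) grid.

    sigma = 0 rows use the closed-form corner-collision band; sigma > 0
    cells are classified by the transfer-operator second eigenvalue.  The
    map depends on frequencies only through r = f/F, so the grid is
    F-independent."""
    fixed = dict(fixed or {})
    axis_values = np.asarray(axis_values, dtype=float)
    r_values = np.asarray(r_values, dtype=float)
    if axis_name not in ("g_e", "g_i"):
        raise ValueError("axis_name must be 'g_e' or 'g_i'")
    ent = np.zeros((axis_values.size, r_values.size), dtype=bool)
    for i, a in enumerate(axis_values):
        g_e = a if axis_name == "g_e" else fixed.get("g_e", 0.0)
        g_i = a if axis_name == "g_i" else fixed.get("g_i", 0.0)
        if sigma == 0:
            ent[i] = deterministic_band(law, g_e, g_i).contains(r_values)
        else:
            for j, r in enumerate(r_values):
                cfg = PhaseMapConfig(F_hz=F_hz, f_hz=F_hz * r, law=law,
                                     g_e_nS=g_e, g_i_nS=g_i, sigma=sigma)
                tm = build_transition_matrix(cfg, n_bins)
                ent[i, j] = stochastic_classify(tm)[0] == "entrained"
    return Tongue(axis_name=axis_name, axis_values=axis_values,
                  r_values=r_values, entrained=ent, sigma=sigma,
                  fixed=fixed, law=law, n_bins=n_bins)


def area_ratio(law: SPRFLaw, axis_name: str, axis_values, r_values,
               sigma: float, fixed: dict | None = None,
               n_bins: int = 256) -> float:
    """Stochastic-to-deterministic entrainment area ratio on one grid."""
    det = tongue(law, axis_name, axis_values, r_values, 0.0, fixed, n_bins)
    if det.area == 0:
        raise ValueError("deterministic tongue has zero area on this grid")
    sto = tongue(law, axis_name, axis_values, r_values, sigma, fixed, n_bins)
    return sto.area / det.area


#: grid used for the headline noise-shrinkage analysis: g_e axis at
#: g_i = 1.5 nS, frequency ratio 0.6-1.6
DEFAULT_GE_PLANE = {
    "axis_name": "g_e",
    "axis_values": np.linspace(0.0, 1.5, 60),
    "r_values": np.linspace(0.6, 1.6, 100),
    "fixed": {"g_i": 1.5},
}
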