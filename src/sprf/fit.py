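"""Piecewise-linear SPRF model, fitting, and the synaptic-strength law.

The SPRF of an FS cell under compound gap/GABA input is well approximated
by two anchored line segments separated by a sharp break at the critical
phase phi_c (phases and shifts in cycles):

    dphi(phi) = -beta * phi          for 0 <= phi <  phi_c   (delay)
    dphi(phi) =  alpha * (1 - phi)   for phi_c <= phi < 1    (advance)

Three free parameters: the delay slope magnitude beta, the advance slope
magnitude alpha, and the breakpoint phi_c.  The function is anchored at
dphi(0) = 0 and dphi(1-) = 0 and is in general DIScontinuous at phi_c.

Across synaptic strengths the parameters follow a simple law:

    beta  = a * g_i,   alpha = b * g_e,   phi_c = c - d * g_e

with a, b in 1/nS and c, d in cycles and cycles/nS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PiecewiseSPRF:
    """Anchored two-segment SPRF with slopes alpha, beta >= 0 and
    breakpoint phi_c in (0, 1)."""

    alpha: float
    beta: float
    phi_c: float

    def __post_init__(self):
        if not (0.0 < self.phi_c < 1.0):
            raise ValueError("phi_c must lie in (0, 1)")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("slope magnitudes must be >= 0")
        if self.alpha >= 1 or self.beta >= 1:
            warnings.warn("slope magnitude >= 1: the entrained fixed point "
                          "of the phase map is unstable", stacklevel=2)

    def __call__(self, phi):
        phi = np.asarray(phi, dtype=float)
        out = np.where(phi < self.phi_c, -self.beta * phi,
                       self.alpha * (1.0 - phi))
        return out if out.ndim else float(out)

    @property
    def min_dphi(self) -> float:
        """Largest delay the SPRF can produce (at phi_c-)."""
        return -self.beta * self.phi_c

    @property
    def max_dphi(self) -> float:
        """Largest advance the SPRF can produce (at phi_c)."""
        return self.alpha * (1.0 - self.phi_c)


@dataclass(frozen=True)
class SPRFLaw:
    """Linear dependence of the SPRF parameters on synaptic strengths."""

    a: float  # delay slope per nS of g_i
    b: float  # advance slope per nS of g_e
    c: float  # breakpoint at g_e = 0 (cycles)
    d: float  # breakpoint shift per nS of g_e (cycles/nS)

    def __post_init__(self):
        if self.a < 0 or self.b < 0 or self.d < 0:
            raise ValueError("a, b, d must be >= 0")
        if not (0.0 < self.c <= 1.0):
            raise ValueError("c must lie in (0, 1]")

    def evaluate(self, g_e: float, g_i: float) -> PiecewiseSPRF:
        phi_c = self.c - self.d * g_e
        if not (0.0 < phi_c < 1.0):
            warnings.warn(f"phi_c = {phi_c:.3f} outside (0,1) at g_e={g_e}; "
                          "clamping", stacklevel=2)
            phi_c = min(max(phi_c, 1e-6), 1.0 - 1e-6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return PiecewiseSPRF(alpha=self.b * g_e, beta=self.a * g_i,
                                 phi_c=phi_c)


#: law printed for the tongue/bifurcation analyses
REFERENCE_LAW = SPRFLaw(a=0.12, b=0.625, c=0.8, d=0.2)
#: population-mean slopes from the dynamic-clamp measurements
MEAN_LAW = SPRFLaw(a=0.16, b=0.69, c=0.8, d=0.2)


@dataclass
class FitDiagnostics:
    phi_c_candidates: np.ndarray
    sse: float
    residuals: np.ndarray          # on all samples, from the final fit
    kept_idx: np.ndarray
    removed_idx: np.ndarray
    alpha_raw: float
    beta_raw: float
    alpha_se: float
    beta_se: float
    intercepts: tuple = (0.0, 0.0)
    chi2: float = np.nan
    chi2_red: float = np.nan
    p_value: float = np.nan


def grubbs_critical(n: int, alpha_level: float = 0.05) -> float:
    """Two-sided Grubbs critical value G for sample size n."""
    t = stats.t.ppf(1.0 - alpha_level / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_filter(residuals, alpha_level: float = 0.05,
                  max_remove: int = 3) -> np.ndarray:
    """Iterative two-sided Grubbs outlier test; returns kept indices.

    At most ``max_remove`` points are removed (occasional outliers only —
    in most curves none).  Constant residuals are all kept (zero-variance
    guard).
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.size < 7:
        raise ValueError("need at least 7 residuals for outlier testing")
    keep = np.arange(residuals.size)
    for _ in range(max_remove):
        r = residuals[keep]
        sd = r.std(ddof=1)
        if sd == 0 or r.size < 3:
            break
        z = np.abs(r - r.mean()) / sd
        imax = int(np.argmax(z))
        if z[imax] > grubbs_critical(r.size, alpha_level):
            keep = np.delete(keep, imax)
        else:
            break
    return keep


def _branch_fit(phi, dphi, phi_c, anchored=True):
    """Least-squares slopes for both branches at a fixed breakpoint.

    Returns (alpha, beta, intercepts, sse, raw) where ``raw`` carries the
    unconstrained slope estimates.  Anchored: delay through (0,0) with
    regressor -phi; advance through (1,0) with regressor (1-phi); slopes
    clamped at 0 (constrained least squares in the model space).
    """
    dmask = phi < phi_c
    amask = ~dmask
    b_int = a_int = 0.0
    sse = 0.0
    beta = alpha = 0.0
    beta_raw = alpha_raw = 0.0
    if dmask.any():
        x, y = phi[dmask], dphi[dmask]
        if anchored:
            sxx = np.dot(x, x)
            # constrained LS: slope magnitudes are >= 0 in the model space,
            # and the SSE is quadratic, so clamping at 0 is the optimum
            beta_raw = 0.0 if sxx == 0 else -np.dot(x, y) / sxx
            beta = max(beta_raw, 0.0)
            sse += float(np.sum((y + beta * x) ** 2))
        else:
            A = np.column_stack([-x, np.ones_like(x)])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            beta, b_int = coef[0], coef[1]
            beta_raw = beta
            sse += float(np.sum((y - A @ coef) ** 2))
    if amask.any():
        x, y = 1.0 - phi[amask], dphi[amask]
        if anchored:
            sxx = np.dot(x, x)
            alpha_raw = 0.0 if sxx == 0 else np.dot(x, y) / sxx
            alpha = max(alpha_raw, 0.0)
            sse += float(np.sum((y - alpha * x) ** 2))
        else:
            A = np.column_stack([x, np.ones_like(x)])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            alpha, a_int = coef[0], coef[1]
            alpha_raw = alpha
            sse += float(np.sum((y - A @ coef) ** 2))
    return alpha, beta, (b_int, a_int), sse, (alpha_raw, beta_raw)


def _slope_se(x, resid, n_params=1):
    n = x.size
    if n <= n_params:
        return np.nan
    s2 = np.sum(resid ** 2) / (n - n_params)
    sxx = np.dot(x, x)
    return np.sqrt(s2 / sxx) if sxx > 0 else np.nan


def fit_piecewise(curve_or_phi, dphi=None, phi_c_grid=None,
                  alpha_level: float = 0.05, max_remove: int = 3,
                  anchored: bool = True):
    """Fit the anchored piecewise-linear SPRF to (phi, dphi) samples.

    The breakpoint is profiled over candidate values (by default the
    midpoints between consecutive sorted sample phases — the exact profile
    set, since the SSE is piecewise-constant in phi_c between samples);
    each branch is an anchored one-parameter least-squares fit.  Ties in
    SSE are broken toward the larger phi_c.  Grubbs outlier rejection is
    applied to the best fit's residuals, and the fit is repeated on the
    kept samples.

    Returns ``(PiecewiseSPRF, FitDiagnostics)``.  Accepts either an
    SPRFCurve (stores the fit on it) or two arrays.
    """
    curve = None
    if dphi is None:
        curve = curve_or_phi
        phi, dphi = curve.phi, curve.dphi
    else:
        phi = np.asarray(curve_or_phi, dtype=float)
        dphi = np.asarray(dphi, dtype=float)
    if phi.size < 8:
        raise ValueError("need at least 8 samples to fit the SPRF")

    def candidates(p, min_per_branch=3):
        # midpoints between consecutive sample phases, keeping at least
        # min_per_branch samples on each side (guards the advance-branch
        # slope against 1-2 point overfits near the cycle end)
        ps = np.sort(np.unique(p))
        mids = 0.5 * (ps[:-1] + ps[1:])
        mids = mids[(mids > 0) & (mids < 1)]
        counts_lo = np.searchsorted(np.sort(p), mids, side="left")
        ok = (counts_lo >= min_per_branch) &              (p.size - counts_lo >= min_per_branch)
        if ok.any():
            mids = mids[ok]
        if mids.size == 0:
            raise ValueError("breakpoint unidentifiable: all samples on one "
                             "side of every candidate breakpoint")
        return mids

    def profile(p, d, cands):
        best = None
        for pc in cands:  # increasing order: later candidate wins ties
            alpha, beta, ints, sse, raw = _branch_fit(p, d, pc, anchored)
            if best is None or sse <= best[0] + 1e-15:
                best = (sse, pc, alpha, beta, ints, raw)
        return best

    if phi_c_grid is None:
        cands = candidates(phi)
    else:
        cands = np.sort(np.asarray(phi_c_grid, dtype=float))
    sse, pc, alpha_fit, beta_fit, ints, raw = profile(phi, dphi, cands)

    # outlier rejection on residuals of the best fit, then refit
    model0 = _model_of(alpha_fit, beta_fit, pc, ints, anchored)
    resid0 = dphi - model0(phi)
    kept = grubbs_filter(resid0, alpha_level, max_remove)
    removed = np.setdiff1d(np.arange(phi.size), kept)
    if removed.size:
        cands2 = cands if phi_c_grid is not None else candidates(phi[kept])
        sse, pc, alpha_fit, beta_fit, ints, raw = profile(phi[kept],
                                                          dphi[kept], cands2)

    alpha_raw, beta_raw = raw
    model = _model_of(alpha_fit, beta_fit, pc, ints, anchored)
    resid = dphi - model(phi)
    dmask = phi[kept] < pc
    alpha_se = _slope_se(1.0 - phi[kept][~dmask], resid[kept][~dmask],
                         1 if anchored else 2)
    beta_se = _slope_se(phi[kept][dmask], resid[kept][dmask],
                        1 if anchored else 2)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = PiecewiseSPRF(alpha=max(alpha_fit, 0.0),
                               beta=max(beta_fit, 0.0), phi_c=pc)
    diag = FitDiagnostics(
        phi_c_candidates=np.asarray(cands), sse=sse, residuals=resid,
        kept_idx=kept, removed_idx=removed, alpha_raw=alpha_raw,
        beta_raw=beta_raw, alpha_se=alpha_se, beta_se=beta_se,
        intercepts=ints)
    if curve is not None:
        curve.fit = result
        curve.diagnostics = diag
    return result, diag


def _model_of(alpha, beta, pc, ints, anchored):
    if anchored:
        def f(p):
            return np.where(p < pc, -beta * p, alpha * (1.0 - p))
    else:
        b0, a0 = ints

        def f(p):
            return np.where(p < pc, -beta * p + b0, alpha * (1.0 - p) + a0)
    return f


def chisq_gof(residuals, sigma2: float, n_params: int = 3,
              kept_idx=None) -> tuple[float, float, float]:
    """Chi-square goodness of fit of an SPRF fit.

    chi2 = sum(residual^2) / sigma2 over kept samples, with sigma2 the
    unperturbed phase variance (cycles^2) measured in the same experiment;
    dof = n_kept - 3 for the three SPRF parameters.  Returns
    (chi2, reduced chi2, upper-tail p).  A fit is "adequate" when the
    data show no significant difference from the model at p >= 0.05.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    residuals = np.asarray(residuals, dtype=float)
    if kept_idx is not None:
        residuals = residuals[np.asarray(kept_idx)]
    dof = residuals.size - n_params
    if dof <= 0:
        raise ValueError("non-positive degrees of freedom")
    chi2 = float(np.sum(residuals ** 2) / sigma2)
    return chi2, chi2 / dof, float(stats.chi2.sf(chi2, dof))


def fit_law(fits) -> SPRFLaw:
    """Regress the synaptic-strength law from per-condition fits.

    ``fits`` is an iterable of (g_e, g_i, PiecewiseSPRF).  a is the
    through-origin slope of beta on g_i, b of alpha on g_e; (c, d) come
    from a straight line (with intercept) of phi_c on g_e.
    """
    fits = list(fits)
    g_e = np.array([f[0] for f in fits], dtype=float)
    g_i = np.array([f[1] for f in fits], dtype=float)
    alpha = np.array([f[2].alpha for f in fits])
    beta = np.array([f[2].beta for f in fits])
    phi_c = np.array([f[2].phi_c for f in fits])
    if np.unique(g_e).size < 3:
        raise ValueError("need >= 3 distinct g_e values")
    if np.unique(g_i).size < 3:
        raise ValueError("need >= 3 distinct g_i values")

    def through_origin(x, y):
        sxx = np.dot(x, x)
        return 0.0 if sxx == 0 else float(np.dot(x, y) / sxx)

    a = through_origin(g_i, beta)
    b = through_origin(g_e, alpha)
    slope, intercept = np.polyfit(g_e, phi_c, 1)
    return SPRFLaw(a=max(a, 0.0), b=max(b, 0.0), c=float(intercept),
                   d=max(float(-slope), 0.0))


def sample_sprf(model: PiecewiseSPRF, n: int = 60, noise_sd: float = 0.0,
                seed=None, phases=None):
    """Synthetic (phi, dphi) samples from a piecewise SPRF with Gaussian
    phase noise — the generator for fit-recovery and chi-square
    calibration studies."""
    rng = np.random.default_rng(seed)
    if phases is None:
        phases = rng.uniform(0.0, 1.0, n)
    phases = np.asarray(phases, dtype=float)
    dphi = model(phases)
    if noise_sd > 0:
        dphi = dphi + rng.normal(0.0, noise_sd, phases.size)
    return phases, dphi
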