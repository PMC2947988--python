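import numpy as np
import pytest

from sprf.fit import REFERENCE_LAW, SPRFLaw
from sprf.phase_map import PhaseMapConfig, deterministic_image, iterate_phases
from sprf.bifurcation import (Tongue, area_ratio, build_transition_matrix,
                              deterministic_band, stochastic_classify, tongue)


def map_cfg(r, g_e=0.75, g_i=1.5, sigma=0.05, law=REFERENCE_LAW):
    return PhaseMapConfig(F_hz=40.0, f_hz=40.0 * r, law=law, g_e_nS=g_e,
                          g_i_nS=g_i, sigma=sigma)


class TestDeterministicBand:
    def test_closed_form_at_reference_parameters(self):
        b = deterministic_band(REFERENCE_LAW, 0.75, 1.5)
        assert b.beta == pytest.approx(0.18)
        assert b.alpha == pytest.approx(0.46875)
        assert b.phi_c == pytest.approx(0.65)
        assert b.r_lo == pytest.approx(1 / 1.117, abs=2e-4)
        assert b.r_hi == pytest.approx(1 / 0.8359375, abs=2e-4)

    def test_no_inhibition_no_entrainment_below_F(self):
        b = deterministic_band(REFERENCE_LAW, 0.5, 0.0)
        assert b.r_lo == 1.0

    def test_no_gap_no_entrainment_above_F(self):
        b = deterministic_band(REFERENCE_LAW, 0.0, 2.0)
        assert b.r_hi == 1.0

    def test_band_shrinks_to_point_as_coupling_vanishes(self):
        widths = [deterministic_band(REFERENCE_LAW, s * 0.75, s * 1.5).width
                  for s in (1.0, 0.5, 0.1, 0.01)]
        assert all(np.diff(widths) < 0)
        assert widths[-1] < 0.01

    def test_brute_force_fixed_point_scan_agrees_exactly(self):
        """Oracle equivalence: existence of a fixed point on a dense phase
        scan matches the closed-form band for 200 random parameter sets."""
        rng = np.random.default_rng(1234)
        phi = np.linspace(0.0, 1.0, 10000, endpoint=False)
        for _ in range(200):
            law = SPRFLaw(a=rng.uniform(0.02, 0.3), b=rng.uniform(0.1, 0.9),
                          c=rng.uniform(0.55, 0.95), d=rng.uniform(0.0, 0.3))
            g_e = rng.uniform(0.0, 1.2)
            g_i = rng.uniform(0.0, 3.0)
            r = rng.uniform(0.6, 1.6)
            band = deterministic_band(law, g_e, g_i)
            cfg = PhaseMapConfig(F_hz=40.0, f_hz=40.0 * r, law=law,
                                 g_e_nS=g_e, g_i_nS=g_i)
            g = deterministic_image(phi, cfg) - 1.0 - phi  # dphi + F/f - 1
            m = cfg.sprf
            delay = phi < m.phi_c
            exists = False
            for mask in (delay, ~delay):
                if mask.any() and g[mask].min() <= 0 <= g[mask].max():
                    exists = True
            assert exists == bool(band.contains(r)), (law, g_e, g_i, r)


class TestTransitionMatrix:
    def test_columns_stochastic_and_leading_eigenvalue_one(self):
        tm = build_transition_matrix(map_cfg(1.05), 128)
        assert np.allclose(tm.matrix.sum(axis=0), 1.0, atol=1e-12)
        ev = tm.eigenvalues()
        assert abs(ev[0] - 1.0) < 1e-10
        assert np.all(np.abs(ev) <= 1 + 1e-10)

    def test_identity_map_has_uniform_stationary_distribution(self):
        cfg = map_cfg(1.0, g_e=0.0, g_i=0.0, sigma=0.03)
        tm = build_transition_matrix(cfg, 128)
        rho = tm.stationary_distribution()
        assert np.allclose(rho, 1.0 / 128, atol=1e-6)

    def test_second_eigenvalue_converges_under_bin_refinement(self):
        cfg = map_cfg(1.05, sigma=0.05)
        l2_256 = stochastic_classify(build_transition_matrix(cfg, 256))[1]
        l2_512 = stochastic_classify(build_transition_matrix(cfg, 512))[1]
        assert abs(l2_256 - l2_512) < 1e-3

    def test_stationary_distribution_matches_simulation(self):
        """Invariant density from the operator vs a histogram of 1e6 map
        iterates: total-variation distance below 0.02."""
        cfg = PhaseMapConfig(F_hz=40.0, f_hz=42.0, law=REFERENCE_LAW,
                             g_e_nS=0.75, g_i_nS=1.5, sigma=0.05, seed=99)
        n_bins = 256
        tm = build_transition_matrix(cfg, n_bins)
        rho = tm.stationary_distribution()
        phases = iterate_phases(cfg, 1_000_000, discard=5000)
        hist, _ = np.histogram(phases, bins=n_bins, range=(0, 1))
        hist = hist / hist.sum()
        tv = 0.5 * np.abs(rho - hist).sum()
        assert tv < 0.02

    def test_sigma_zero_rejected(self):
        with pytest.raises(ValueError):
            build_transition_matrix(map_cfg(1.0, sigma=0.0), 128)

    def test_minimum_bin_count_enforced(self):
        with pytest.raises(ValueError):
            build_transition_matrix(map_cfg(1.0), 64)


class TestStochasticClassification:
    def test_entrained_inside_band(self):
        lab, lam2 = stochastic_classify(
            build_transition_matrix(map_cfg(1.05, sigma=0.02), 256))
        assert lab == "entrained"
        assert lam2.imag == pytest.approx(0.0, abs=1e-8)
        assert lam2.real > 0

    def test_drifting_outside_band(self):
        # 20% detuning beyond the upper corner at sigma = 0.02
        r = deterministic_band(REFERENCE_LAW, 0.75, 1.5).r_hi * 1.2
        lab, lam2 = stochastic_classify(
            build_transition_matrix(map_cfg(r, sigma=0.02), 256))
        assert lab == "drifting"
        assert abs(lam2.imag) > 1e-6

    def test_boundary_converges_to_deterministic_corners(self):
        """As sigma -> 0 the classification boundary approaches the
        corner-collision frequencies; at sigma <= 0.005 it lies within one
        0.02-wide frequency-ratio grid step, and the offset shrinks with
        sigma."""
        band = deterministic_band(REFERENCE_LAW, 0.75, 1.5)
        step = 0.02

        def entrained(rr, sigma):
            tm = build_transition_matrix(map_cfg(float(rr), sigma=sigma), 256)
            return stochastic_classify(tm)[0] == "entrained"

        offsets = {}
        for sigma in (0.02, 0.005):
            lo = next(rr for rr in np.arange(0.88, 1.0, 0.002)
                      if entrained(rr, sigma))
            hi = next(rr for rr in np.arange(1.21, 1.0, -0.002)
                      if entrained(rr, sigma))
            offsets[sigma] = (lo - band.r_lo, band.r_hi - hi)
        # inward displacement scales like a few sigma: within one grid
        # step at sigma <= 0.005, and shrinking as sigma decreases
        assert max(offsets[0.005]) < step
        assert offsets[0.005][0] < offsets[0.02][0]
        assert offsets[0.005][1] < offsets[0.02][1]


class TestTongues:
    GE_AXIS = np.linspace(0.0, 1.5, 40)
    R_AXIS = np.linspace(0.6, 1.6, 50)

    def test_deterministic_tongue_matches_closed_form(self):
        t = tongue(REFERENCE_LAW, "g_e", self.GE_AXIS, self.R_AXIS, sigma=0.0,
                   fixed={"g_i": 1.5})
        for i, g_e in enumerate(self.GE_AXIS):
            band = deterministic_band(REFERENCE_LAW, g_e, 1.5)
            assert np.array_equal(t.entrained[i], band.contains(self.R_AXIS))

    def test_width_nondecreasing_in_ge(self):
        # exact band widths grow monotonically with electrical coupling;
        # grid cell counts may jitter by one cell from discretization
        widths = np.array([deterministic_band(REFERENCE_LAW, g, 1.5).width
                           for g in self.GE_AXIS])
        assert np.all(np.diff(widths) > 0)
        t = tongue(REFERENCE_LAW, "g_e", self.GE_AXIS, self.R_AXIS, sigma=0.0,
                   fixed={"g_i": 1.5})
        counts = t.entrained.sum(axis=1)
        assert np.all(np.diff(counts) >= -1)

    def test_area_accounting_is_exact(self):
        t = tongue(REFERENCE_LAW, "g_e", self.GE_AXIS, self.R_AXIS, sigma=0.0,
                   fixed={"g_i": 1.5})
        assert t.area == t.entrained.sum() * t.cell_area

    def test_area_ratio_one_at_zero_noise(self):
        r = area_ratio(REFERENCE_LAW, "g_e", self.GE_AXIS, self.R_AXIS, sigma=0.0,
                       fixed={"g_i": 1.5})
        assert r == 1.0

    def test_zero_deterministic_area_rejected(self):
        law = SPRFLaw(a=0.12, b=0.625, c=0.8, d=0.2)
        with pytest.raises(ValueError):
            area_ratio(law, "g_e", np.array([0.0, 0.1]),
                       np.array([2.5, 2.6]), sigma=0.05)

    def test_noise_asymmetry_pure_inhibition(self):
        """With g_e = 0 the lower frequency limit of entrainment is far
        more noise-sensitive than the upper limit."""
        band = deterministic_band(REFERENCE_LAW, 0.0, 3.0)
        r = np.arange(0.70, 1.02, 0.005)
        ent = np.array([
            stochastic_classify(build_transition_matrix(
                map_cfg(float(rr), g_e=0.0, g_i=3.0, sigma=0.05), 256))[0]
            == "entrained" for rr in r])
        idx = np.flatnonzero(ent)
        lo_shift = r[idx[0]] - band.r_lo
        hi_shift = band.r_hi - r[idx[-1]]
        assert lo_shift > hi_shift
        assert lo_shift > 0.03
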