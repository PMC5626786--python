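"""Two-state exchange models: oracles, limits, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nusrd import exchange
from nusrd.quantify import DispersionCurve

NUS = np.array([25., 50., 75., 100., 150., 200., 300., 400., 500., 750., 1000.])
RAD_15N = 2 * np.pi * 81.08          # rad/s per ppm at 18.8 T
T_RELAX = 0.04


class TestForwardModels:
    def test_no_exchange_returns_intrinsic_rate(self):
        assert exchange.bm_r2eff(100.0, 9.5, 182.0, 0.029, 0.0, T_RELAX) == 9.5
        assert exchange.cr_r2eff(100.0, 9.5, 182.0, 0.029, 0.0, T_RELAX) == 9.5
        assert exchange.bm_r2eff(100.0, 9.5, 200.0, 0.0, 500.0, T_RELAX) == 9.5

    def test_vanishing_population_limit(self):
        r = exchange.bm_r2eff(50.0, 12.0, 182.0, 1e-7, 500.0, T_RELAX)
        assert r == pytest.approx(12.0, abs=1e-3)

    def test_dispersion_decreases_with_refocusing_rate(self):
        lo = exchange.bm_r2eff(50.0, 10.0, 182.0, 0.029, 1.0 * RAD_15N, T_RELAX)
        hi = exchange.bm_r2eff(1000.0, 10.0, 182.0, 0.029, 1.0 * RAD_15N, T_RELAX)
        assert lo > hi
        lo_c = float(exchange.cr_r2eff(25.0, 10.0, 182.0, 0.029, 2 * RAD_15N, T_RELAX))
        hi_c = float(exchange.cr_r2eff(1000.0, 10.0, 182.0, 0.029, 2 * RAD_15N, T_RELAX))
        assert lo_c > hi_c

    def test_monotone_nonincreasing_over_grid(self):
        vals = [exchange.bm_r2eff(nu, 10.0, 182.0, 0.029, 1.5 * RAD_15N, T_RELAX)
                for nu in NUS]
        diffs = np.diff(vals)
        assert np.all(diffs <= 1e-9)

    def test_large_nu_closer_to_intrinsic_than_small_nu(self):
        r0 = 10.0
        far = exchange.bm_r2eff(4000.0, r0, 182.0, 0.029, 1.0 * RAD_15N, T_RELAX)
        near = exchange.bm_r2eff(25.0, r0, 182.0, 0.029, 1.0 * RAD_15N, T_RELAX)
        assert abs(far - r0) < abs(near - r0)

    def test_fast_exchange_matches_luz_meiboom(self):
        kex, p_b, dw = 2000.0, 0.03, 300.0
        phi = (1 - p_b) * p_b * dw**2
        bm = exchange.bm_r2eff(25.0, 10.0, kex, p_b, dw, T_RELAX)
        lm = float(exchange.luz_meiboom_r2eff(25.0, 10.0, phi, kex))
        assert bm == pytest.approx(lm, rel=0.01)

    def test_fast_exchange_low_nu_plateau(self):
        # R2(nu->0) - r2_0 ~ p_a p_b dw^2 / kex in fast exchange
        kex, p_b, dw = 5000.0, 0.03, 400.0
        plateau = (1 - p_b) * p_b * dw**2 / kex
        bm = exchange.bm_r2eff(10.0, 10.0, kex, p_b, dw, T_RELAX)
        assert bm - 10.0 == pytest.approx(plateau, rel=0.05)

    def test_closed_form_matches_propagator_over_parameter_box(self):
        rng = np.random.default_rng(11)
        worst = 0.0
        for _ in range(1000):
            kex = float(np.exp(rng.uniform(np.log(50), np.log(2000))))
            p_b = float(rng.uniform(0.005, 0.1))
            dw = float(rng.uniform(0.0, 4.0)) * RAD_15N
            r20 = float(rng.uniform(5, 25))
            nu = float(rng.choice(NUS))
            bm = exchange.bm_r2eff(nu, r20, kex, p_b, dw, T_RELAX)
            cr = float(exchange.cr_r2eff(nu, r20, kex, p_b, dw, T_RELAX))
            worst = max(worst, abs(cr - bm) / max(bm, 1e-12))
        assert worst < 0.02

    def test_classical_cr72_in_fast_exchange(self):
        bm = exchange.bm_r2eff(100.0, 10.0, 2000.0, 0.03, 300.0, T_RELAX)
        cr = float(exchange.cr72_r2eff(100.0, 10.0, 2000.0, 0.03, 300.0))
        assert cr == pytest.approx(bm, rel=0.02)

    @given(st.floats(50, 2000), st.floats(0.005, 0.1), st.floats(0.05, 4.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_rates_bounded_below_by_intrinsic(self, kex, p_b, dw_ppm):
        r = exchange.bm_r2eff(100.0, 8.0, kex, p_b, dw_ppm * RAD_15N, T_RELAX)
        assert r >= 8.0 - 1e-9


class TestResidueFit:
    def test_flat_noiseless_curve(self):
        fit = exchange.fit_residue(NUS, np.full(len(NUS), 11.0),
                                   np.full(len(NUS), 0.2))
        assert fit.flat_rmsd == pytest.approx(0.0, abs=1e-12)
        assert not fit.significant

    def test_strong_exchanger_is_significant(self):
        # power check: median p over noise draws is deep below the threshold
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(20):
            y = exchange.cr_r2eff(NUS, 10.0, 182.0, 0.029, 2.0 * RAD_15N, T_RELAX)
            y = y + 0.2 * rng.standard_normal(len(NUS))
            ps.append(exchange.fit_residue(NUS, y, np.full(len(NUS), 0.2)).p_value)
        assert np.median(ps) < 1e-6
        assert max(ps) < 1e-4

    def test_type_one_error_calibrated(self):
        # flat curves must be rejected at p<0.01 about 1% of the time
        rng = np.random.default_rng(7)
        sigma = np.full(len(NUS), 0.2)
        n, rej = 5000, 0
        for _ in range(n):
            y = 12.0 + 0.2 * rng.standard_normal(len(NUS))
            rej += exchange.fit_residue(NUS, y, sigma).significant
        assert 0.005 <= rej / n <= 0.015

    def test_degenerate_errors_warn_and_fall_back(self):
        with pytest.warns(UserWarning, match="unweighted"):
            fit = exchange.fit_residue(NUS, np.full(len(NUS), 9.0),
                                       np.zeros(len(NUS)))
        assert fit.unweighted

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            exchange.fit_residue(NUS[:4], np.ones(4), np.ones(4))


def _make_curves(rng, n_res=8, kex=182.0, p_b=0.029, sigma=0.2):
    curves = []
    dws = rng.uniform(0.3, 3.0, n_res)
    r20s = rng.uniform(8, 16, n_res)
    for i in range(n_res):
        y = exchange.cr_r2eff(NUS, r20s[i], kex, p_b, dws[i] * RAD_15N, T_RELAX)
        y = y + sigma * rng.standard_normal(len(NUS))
        curves.append(DispersionCurve(f"R{i:03d}", NUS.copy(), y,
                                      np.full(len(NUS), sigma), T_RELAX))
    return curves, dws, r20s


class TestGlobalFit:
    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(5)
        curves, dws, r20s = _make_curves(rng, sigma=0.0)
        for c in curves:
            c.sigma = np.full(len(NUS), 0.05)  # weights only
        fit = exchange.fit_global(curves, obs_mhz=81.08, starts=8, seed=0)
        assert fit.params.kex == pytest.approx(182.0, rel=1e-4)
        assert fit.params.p_b == pytest.approx(0.029, rel=1e-4)
        for i, pid in enumerate(c.peak_id for c in curves):
            assert fit.params.dw_ppm[pid] == pytest.approx(dws[i], rel=1e-3)

    def test_noisy_recovery_within_uncertainty(self):
        rng = np.random.default_rng(6)
        curves, _, _ = _make_curves(rng, n_res=14)
        fit = exchange.fit_global(curves, obs_mhz=81.08, starts=10, seed=0)
        assert abs(fit.params.kex - 182.0) < 3 * fit.kex_err
        assert abs(fit.params.p_b - 0.029) < 3 * fit.p_b_err
        assert not fit.boundary_pinned

    def test_duplicated_curves_leave_estimate_unchanged(self):
        rng = np.random.default_rng(8)
        curves, _, _ = _make_curves(rng, n_res=4)
        fit1 = exchange.fit_global(curves, obs_mhz=81.08, starts=6, seed=0)
        doubled = curves + [
            DispersionCurve(c.peak_id + "b", c.nu.copy(), c.r2eff.copy(),
                            c.sigma.copy(), c.t_relax)
            for c in curves
        ]
        fit2 = exchange.fit_global(doubled, obs_mhz=81.08, starts=6, seed=0)
        assert fit2.params.kex == pytest.approx(fit1.params.kex, rel=1e-3)
        assert fit2.params.p_b == pytest.approx(fit1.params.p_b, rel=1e-3)

    def test_needs_two_residues(self):
        rng = np.random.default_rng(9)
        curves, _, _ = _make_curves(rng, n_res=1)
        with pytest.raises(ValueError):
            exchange.fit_global(curves, obs_mhz=81.08)

    def test_covariance_reports_population_rate_coupling(self):
        rng = np.random.default_rng(10)
        curves, _, _ = _make_curves(rng, n_res=10)
        fit = exchange.fit_global(curves, obs_mhz=81.08, starts=8, seed=0)
        assert fit.covariance is not None
        corr = fit.covariance[0, 1] / np.sqrt(
            fit.covariance[0, 0] * fit.covariance[1, 1])
        assert abs(corr) > 0.2  # kex / p_b are strongly coupled


class TestDwRmsd:
    def test_identical_lists(self):
        assert exchange.dw_rmsd([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_simple_value(self):
        assert exchange.dw_rmsd([1.0], [1.2]) == pytest.approx(0.2)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            exchange.dw_rmsd([1.0], [1.0, 2.0])
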