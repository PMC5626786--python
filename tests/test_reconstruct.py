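"""Reconstruction paths: reference FT, co-MDD decomposition, IRLS-VE."""

import numpy as np
import pytest

from nusrd import pipeline, quantify
from nusrd.acquisition import (GridSpec, apply_schedule, generate_schedule,
                               synthesize_fid)
from nusrd.reconstruct import (comdd_fit, comdd_reconstruct, full_ft,
                               irls_ve_reconstruct, virtual_echo)
from nusrd.systems import CpmgSeriesSpec, ExchangeSite, ExchangeSystem


class TestFullFT:
    def test_single_site_peak_at_expected_position(self, clean_one_site,
                                                   one_site_system):
        spectra = full_ft(clean_one_site)
        site = one_site_system.sites[0]
        expect = spectra.index_of(site.position_ppm)
        for p in range(spectra.n_planes):
            found = np.unravel_index(np.argmax(spectra.values[p]),
                                     spectra.values[p].shape)
            assert all(abs(a - b) <= 1 for a, b in zip(found, expect))

    def test_linearity(self, small_grid, spec_15n):
        s1 = ExchangeSite("a", (-0.2, -4.0), (15.0, 8.0), 8.0, 0.0, 1.0)
        s2 = ExchangeSite("b", (0.3, 5.0), (18.0, 9.0), 9.0, 0.0, 0.7)
        d1 = synthesize_fid(ExchangeSystem([s1], 0, 0, flat=True),
                            small_grid, spec_15n, 0.0)
        d2 = synthesize_fid(ExchangeSystem([s2], 0, 0, flat=True),
                            small_grid, spec_15n, 0.0)
        both = synthesize_fid(ExchangeSystem([s1, s2], 0, 0, flat=True),
                              small_grid, spec_15n, 0.0)
        np.testing.assert_allclose(
            full_ft(both).values,
            full_ft(d1).values + full_ft(d2).values,
            rtol=0, atol=1e-10 * np.abs(full_ft(both).values).max(),
        )

    def test_flat_system_planes_proportional(self, clean_one_site):
        spectra = full_ft(clean_one_site)
        v = spectra.values
        for p in range(2, spectra.n_planes):
            ratio = v[p] / np.where(np.abs(v[1]) > 1e-12 * np.abs(v[1]).max(),
                                    v[1], np.nan)
            med = np.nanmedian(ratio)
            assert med == pytest.approx(1.0, abs=1e-10)

    def test_requires_full_mask(self, clean_one_site, small_grid):
        sched = generate_schedule(small_grid, clean_one_site.n_planes, 0.5, seed=0)
        with pytest.raises(ValueError):
            full_ft(apply_schedule(clean_one_site, sched))


class TestComdd:
    def test_exact_rank_one_recovery(self, clean_one_site):
        model = comdd_fit(clean_one_site, n_components=1, lambda_reg=1e-9, seed=0)
        assert model.rel_residual < 1e-6
        rec = comdd_reconstruct(model)
        ref = full_ft(clean_one_site)
        np.testing.assert_allclose(rec.values, ref.values,
                                   atol=1e-6 * np.abs(ref.values).max())

    def test_rank_two_sparse_cross_validation(self, spec_15n):
        grid = GridSpec(n_direct=64, sw_direct_hz=900.0, n_indirect=(48,),
                        sw_indirect_hz=(2250.0,))
        s1 = ExchangeSite("a", (-0.3, -6.0), (20.0, 10.0), 10.0, 1.0, 1.0)
        s2 = ExchangeSite("b", (0.3, 6.0), (22.0, 12.0), 12.0, 2.0, 0.8)
        sys_ = ExchangeSystem([s1, s2], kex=182.0, p_b=0.029)
        data = synthesize_fid(sys_, grid, spec_15n, 0.0)
        sched = generate_schedule(grid, data.n_planes, 0.25, seed=1)
        sparse = apply_schedule(data, sched)
        model = comdd_fit(sparse, n_components=2, n_iter=2000, seed=0)
        rec = comdd_reconstruct(model)
        ref = full_ft(data)
        # held-out fidelity: reconstructed heights match the fully sampled path
        peaks = quantify.peaklist_from_system(sys_)
        hr = quantify.extract_intensities(rec, peaks).values
        hf = quantify.extract_intensities(ref, peaks).values
        assert np.max(np.abs(hr - hf) / np.abs(hf)) < 1e-3

    def test_zero_amplitudes_give_zero_spectra(self, clean_one_site):
        model = comdd_fit(clean_one_site, n_components=1, seed=0)
        model.amplitudes = np.zeros_like(model.amplitudes)
        rec = comdd_reconstruct(model)
        assert np.all(rec.values == 0)

    def test_amplitude_linearity(self, clean_one_site):
        model = comdd_fit(clean_one_site, n_components=1, seed=0)
        base = comdd_reconstruct(model).values.copy()
        model.amplitudes = 2.0 * model.amplitudes
        np.testing.assert_allclose(comdd_reconstruct(model).values, 2.0 * base,
                                   rtol=1e-12)

    def test_intensity_linearity_against_data_scaling(self, clean_one_site):
        from dataclasses import replace

        scaled = replace(clean_one_site, values=3.0 * clean_one_site.values)
        m1 = comdd_fit(clean_one_site, n_components=1, seed=0)
        m2 = comdd_fit(scaled, n_components=1, seed=0)
        h1 = comdd_reconstruct(m1).values
        h2 = comdd_reconstruct(m2).values
        assert np.max(np.abs(h2 - 3.0 * h1)) < 1e-8 * np.abs(h2).max()

    def test_flat_system_amplitudes_constant_over_planes(self, small_grid, spec_15n,
                                                         one_site_system):
        # CPMG planes of a flat system differ only by the fixed exp(-R2,0 T)
        data = synthesize_fid(one_site_system, small_grid, spec_15n,
                              noise_sigma=0.002, seed=12)
        sched = generate_schedule(small_grid, data.n_planes, 0.4, seed=2)
        sparse = apply_schedule(data, sched)
        model = comdd_fit(sparse, n_components=1, n_iter=500, seed=0)
        amps = np.abs(model.amplitudes[1:, 0])
        assert amps.std() / amps.mean() < 0.02

    def test_empty_plane_rejected(self, clean_one_site):
        bad = clean_one_site
        bad.mask[2] = False
        try:
            with pytest.raises(ValueError):
                comdd_fit(bad, n_components=1, seed=0)
        finally:
            bad.mask[2] = True


class TestVirtualEcho:
    def test_real_even_input_gives_real_spectrum(self):
        v = np.exp(-0.2 * np.arange(16))  # real, no modulation
        ve = virtual_echo(v)
        spec = np.fft.fft(ve)
        assert np.max(np.abs(spec.imag)) < 1e-10 * np.max(np.abs(spec.real))

    def test_delta_gives_flat_spectrum(self):
        v = np.zeros(16, dtype=complex)
        v[0] = 1.0
        spec = np.fft.fft(virtual_echo(v))
        np.testing.assert_allclose(spec.real, 1.0, atol=1e-12)
        np.testing.assert_allclose(spec.imag, 0.0, atol=1e-12)

    def test_damped_cosinusoid_matches_lorentzian(self):
        n, r, f = 256, 30.0, 40.0
        sw = 1000.0
        t = np.arange(n) / sw
        v = np.exp((2j * np.pi * f - r) * t)
        spec = np.fft.fft(virtual_echo(v)).real
        freqs = np.fft.fftfreq(2 * n, 1.0 / sw)
        # analytic absorptive Lorentzian (continuous FT, x2 for the echo)
        peak_idx = np.argmax(spec)
        lor = 2.0 * sw * (r / ((2 * np.pi * (freqs[peak_idx] - f)) ** 2 + r**2))
        assert spec[peak_idx] == pytest.approx(lor, rel=0.02)


class TestIrlsVe:
    def test_fully_sampled_equals_full_ft(self, clean_one_site):
        out = irls_ve_reconstruct(clean_one_site)
        ref = full_ft(clean_one_site)
        np.testing.assert_allclose(out.values, ref.values,
                                   atol=1e-6 * np.abs(ref.values).max())

    def test_sparse_narrow_peak_height_within_one_percent(self, spec_15n):
        grid = GridSpec(n_direct=32, sw_direct_hz=900.0, n_indirect=(48,),
                        sw_indirect_hz=(2250.0,))
        site = ExchangeSite("x", (0.1, 2.0), (20.0, 4.0), 10.0, 0.0, 1.0)
        sys_ = ExchangeSystem([site], 0.0, 0.0, flat=True)
        data = synthesize_fid(sys_, grid, spec_15n, 0.0)
        sched = generate_schedule(grid, data.n_planes, 0.25, seed=2)
        out = irls_ve_reconstruct(apply_schedule(data, sched))
        ref = full_ft(data)
        peaks = quantify.peaklist_from_system(sys_)
        hi = quantify.extract_intensities(out, peaks).values
        hf = quantify.extract_intensities(ref, peaks).values
        assert np.max(np.abs(hi - hf) / np.abs(hf)) < 0.01

    def test_all_zero_data_reconstructs_zero(self, clean_one_site, small_grid):
        from dataclasses import replace

        zero = replace(
            clean_one_site,
            values=np.zeros_like(clean_one_site.values),
            values_neg=np.zeros_like(clean_one_site.values),
        )
        sched = generate_schedule(small_grid, zero.n_planes, 0.3, seed=1)
        out = irls_ve_reconstruct(apply_schedule(zero, sched))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_three_dimensional_path(self, grid_3d_small, spec_15n):
        spec = CpmgSeriesSpec(nu_hz=(50.0, 200.0, 800.0), nucleus="15N")
        site = ExchangeSite("x", (0.1, 2.0, -1.0), (20.0, 8.0, 6.0), 10.0, 0.0, 1.0)
        sys_ = ExchangeSystem([site], 0.0, 0.0, flat=True)
        data = synthesize_fid(sys_, grid_3d_small, spec, 0.0)
        sched = generate_schedule(grid_3d_small, data.n_planes, 0.3, seed=3)
        out = irls_ve_reconstruct(apply_schedule(data, sched))
        ref = full_ft(data)
        peaks = quantify.peaklist_from_system(sys_)
        hi = quantify.extract_intensities(out, peaks).values
        hf = quantify.extract_intensities(ref, peaks).values
        assert np.max(np.abs(hi - hf) / np.abs(hf)) < 0.05
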