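"""Time-domain synthesis, NUS schedules and the nuslist format."""

import numpy as np
import pytest
from scipy import stats

from nusrd.acquisition import (GridSpec, SamplingSchedule, ScheduleError,
                               apply_schedule, generate_schedule, read_nuslist,
                               synthesize_fid, write_nuslist)
from nusrd.reconstruct import spectral_noise_sigma
from nusrd.systems import CpmgSeriesSpec, ExchangeSite, ExchangeSystem


class TestSynthesize:
    def test_first_point_equals_amplitude(self, clean_one_site, one_site_system):
        # reference plane, t=0 everywhere: DC value of the damped sinusoid
        val = clean_one_site.values[0, 0, 0]
        assert val == pytest.approx(one_site_system.sites[0].amplitude, rel=1e-12)

    def test_flat_system_planes_differ_only_by_decay(self, clean_one_site,
                                                     one_site_system, spec_15n):
        r2_0 = one_site_system.sites[0].r2_0
        scale = np.exp(-r2_0 * spec_15n.t_relax)
        for k in range(1, clean_one_site.n_planes):
            np.testing.assert_allclose(clean_one_site.values[k],
                                       scale * clean_one_site.values[0],
                                       rtol=1e-10)

    def test_peak_appears_at_site_position(self, small_grid, spec_15n):
        site = ExchangeSite("x", (0.25, -5.0), (15.0, 8.0), 8.0, 0.0, 1.0)
        sys_ = ExchangeSystem([site], kex=0.0, p_b=0.0, flat=True)
        data = synthesize_fid(sys_, small_grid, spec_15n, 0.0)
        # FFT the direct dimension of the reference plane's first t1 row
        vec = data.values[0, 0, :]
        spec_d = np.fft.fftshift(np.fft.fft(vec, 4 * small_grid.n_direct))
        freqs = np.fft.fftshift(np.fft.fftfreq(4 * small_grid.n_direct,
                                               1.0 / small_grid.sw_direct_hz))
        peak_hz = freqs[np.argmax(np.abs(spec_d))]
        expect_hz = 0.25 * small_grid.obs_mhz[0]
        assert abs(peak_hz - expect_hz) <= small_grid.sw_direct_hz / (2 * small_grid.n_direct)

    def test_noise_determinism(self, one_site_system, small_grid, spec_15n):
        a = synthesize_fid(one_site_system, small_grid, spec_15n, 0.1, seed=5)
        b = synthesize_fid(one_site_system, small_grid, spec_15n, 0.1, seed=5)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.values_neg, b.values_neg)

    def test_spectral_noise_floor_scaling(self, one_site_system, small_grid, spec_15n):
        # Parseval consistency: measured spectrum noise matches prediction
        from nusrd.reconstruct import full_ft

        sigma = 0.5
        data = synthesize_fid(one_site_system, small_grid, spec_15n, sigma, seed=9)
        clean = synthesize_fid(one_site_system, small_grid, spec_15n, 0.0)
        diff = full_ft(data).values - full_ft(clean).values
        measured = diff.std()
        predicted = spectral_noise_sigma(small_grid, sigma)
        assert measured == pytest.approx(predicted, rel=0.10)


class TestSchedule:
    def test_full_fraction_is_exhaustive(self, small_grid):
        sched = generate_schedule(small_grid, 4, 1.0, seed=0)
        assert len(sched) == small_grid.indirect_size * 4
        assert sched.nus_fraction == 1.0

    def test_too_sparse_raises(self, small_grid):
        with pytest.raises(ScheduleError):
            generate_schedule(small_grid, 12, 0.001, seed=0)

    def test_plane_counts_balanced(self):
        grid = GridSpec(n_direct=8, sw_direct_hz=900.0, n_indirect=(64,),
                        sw_indirect_hz=(2250.0,))
        ratios = []
        for seed in range(100):
            s = generate_schedule(grid, 11, 0.083, seed=seed)
            counts = np.bincount(s.entries[:, -1], minlength=11)
            ratios.append(counts.max() / counts.min())
        assert max(ratios) <= 2.0

    def test_flat_limit_uniform_density(self):
        # t_match >> acquisition time: indirect draw must look uniform
        grid = GridSpec(n_direct=8, sw_direct_hz=900.0, n_indirect=(64,),
                        sw_indirect_hz=(2250.0,))
        counts = np.zeros(64)
        for seed in range(25):
            s = generate_schedule(grid, 25, 0.25, t_match=1e9, seed=seed)
            counts += np.bincount(s.entries[:, 0], minlength=64)
        # exclude the always-sampled anchor point from the uniformity check
        c = counts[1:]
        chi2 = ((c - c.mean()) ** 2 / c.mean()).sum()
        assert stats.chi2.sf(chi2, len(c) - 1) > 0.01

    def test_density_tracks_exponential_weight(self):
        grid = GridSpec(n_direct=8, sw_direct_hz=900.0, n_indirect=(128,),
                        sw_indirect_hz=(2250.0,))
        t_match = 0.01  # strong decay over the acquisition time
        counts = np.zeros(128)
        for seed in range(40):
            s = generate_schedule(grid, 10, 0.2, t_match=t_match, seed=seed,
                                  ensure_coverage=False)
            counts += np.bincount(s.entries[:, 0], minlength=128)
        t = grid.times(1)[1:]
        c = counts[1:]
        # log-density decays linearly with evolution time
        slope = np.polyfit(t[c > 0], np.log(c[c > 0]), 1)[0]
        assert slope == pytest.approx(-1.0 / t_match, rel=0.35)

    def test_marginal_coverage_guaranteed(self, grid_2d):
        for seed in range(10):
            s = generate_schedule(grid_2d, 12, 0.25, seed=seed)
            cov = np.bincount(s.entries[:, 0], minlength=48)
            assert cov.min() >= 1

    def test_determinism(self, small_grid):
        a = generate_schedule(small_grid, 6, 0.3, seed=4)
        b = generate_schedule(small_grid, 6, 0.3, seed=4)
        np.testing.assert_array_equal(a.entries, b.entries)

    def test_coupled_mode_shares_coordinates(self, small_grid):
        s = generate_schedule(small_grid, 4, 0.5, seed=1, coupled=True)
        per_plane = [set(map(tuple, s.entries[s.entries[:, -1] == p][:, :-1]))
                     for p in range(4)]
        assert per_plane[0] == per_plane[1] == per_plane[2] == per_plane[3]


class TestApplySchedule:
    def test_full_schedule_is_identity(self, clean_one_site, small_grid):
        sched = generate_schedule(small_grid, clean_one_site.n_planes, 1.0, seed=0)
        sparse = apply_schedule(clean_one_site, sched)
        np.testing.assert_array_equal(sparse.values, clean_one_site.values)
        assert sparse.fully_sampled

    def test_retains_exactly_scheduled_points(self, clean_one_site, small_grid):
        sched = generate_schedule(small_grid, clean_one_site.n_planes, 0.2, seed=3)
        sparse = apply_schedule(clean_one_site, sched)
        assert int(sparse.mask.sum()) == len(sched)
        assert np.all(sparse.values[~sparse.mask] == 0)

    def test_mismatched_grid_rejected(self, clean_one_site):
        other = GridSpec(n_direct=8, sw_direct_hz=900.0, n_indirect=(16,),
                         sw_indirect_hz=(2250.0,))
        sched = generate_schedule(other, clean_one_site.n_planes, 0.5, seed=0)
        with pytest.raises(ScheduleError):
            apply_schedule(clean_one_site, sched)


class TestNuslist:
    def test_round_trip(self, tmp_path, small_grid):
        sched = generate_schedule(small_grid, 5, 0.3, seed=2)
        path = tmp_path / "nuslist"
        write_nuslist(sched, path)
        back = read_nuslist(path, sched.n_indirect, sched.n_planes)
        np.testing.assert_array_equal(
            np.sort(back.entries, axis=0), np.sort(sched.entries, axis=0))

    def test_line_format(self, tmp_path):
        path = tmp_path / "nuslist"
        path.write_text("3 1\n0 0\n")
        s = read_nuslist(path, (8,), 2)
        assert (3, 1) in {tuple(e) for e in s.entries.tolist()}

    def test_negative_index_rejected(self, tmp_path):
        path = tmp_path / "nuslist"
        path.write_text("0 0\n-1 2\n")
        with pytest.raises(ScheduleError, match="negative"):
            read_nuslist(path, (8,), 4)

    def test_malformed_line_names_position(self, tmp_path):
        path = tmp_path / "nuslist"
        path.write_text("0 0\n1 2 3\n")
        with pytest.raises(ScheduleError, match=":2"):
            read_nuslist(path, (8,), 4)

    def test_schedule_invariants(self):
        with pytest.raises(ScheduleError):
            SamplingSchedule(np.array([[0, 0], [0, 0]]), (8,), 2)  # duplicate
        with pytest.raises(ScheduleError):
            SamplingSchedule(np.array([[9, 0]]), (8,), 1)  # out of range
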