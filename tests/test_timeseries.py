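"""Temporal preprocessing, regional homogeneity, and functional connectivity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adhdkit.timeseries import (
    FcMatrix,
    Parcellation,
    RoiTimecourses,
    Volume4D,
    bandpass_filter,
    compute_fc_matrix,
    compute_reho_map,
    detrend_linear,
    devectorize_fc,
    extract_roi_timecourses,
    kendalls_w,
    neighborhood_footprint,
    prune_fc,
    smooth_map,
    vectorize_fc,
)
from conftest import brute_force_kendalls_w


class TestDetrend:
    def test_constant_series_goes_to_zero(self):
        out = detrend_linear(np.array([[5.0], [5.0], [5.0], [5.0]]))
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_exact_line_goes_to_zero(self):
        out = detrend_linear(np.array([[1.0], [2.0], [3.0], [4.0]]))
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_residuals_match_hand_solved_normal_equations(self):
        # y = [1,3,2,4] on t = 0..3: slope 0.8, intercept 1.3 from the
        # 2-parameter normal equations; residuals follow.
        out = detrend_linear(np.array([[1.0], [3.0], [2.0], [4.0]]))
        assert np.allclose(out[:, 0], [-0.3, 0.9, -0.9, 0.3], atol=1e-12)
        assert abs(out.mean()) < 1e-12

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="3 time points"):
            detrend_linear(np.array([[1.0], [2.0]]))


class TestBandpass:
    tr, n = 2.0, 256

    def _sine(self, hz):
        t = np.arange(self.n) * self.tr
        return np.sin(2 * np.pi * hz * t)

    def test_passband_sinusoid_preserved(self):
        x = self._sine(0.04)
        y = bandpass_filter(x, 0.01, 0.08, tr=self.tr)
        assert np.abs(y).max() >= 0.95 * np.abs(x).max()

    def test_stopband_sinusoid_suppressed(self):
        x = self._sine(0.2)
        y = bandpass_filter(x, 0.01, 0.08, tr=self.tr)
        assert np.abs(y).max() <= 0.1 * np.abs(x).max()

    def test_mixture_reduces_to_passband_component(self):
        x = self._sine(0.04) + self._sine(0.2)
        y = bandpass_filter(x, 0.01, 0.08, tr=self.tr)
        # independent FFT-zeroing oracle on the same series
        freqs = np.fft.rfftfreq(self.n, d=self.tr)
        spec = np.fft.rfft(x)
        spec[(freqs < 0.01) | (freqs > 0.08)] = 0.0
        oracle = np.fft.irfft(spec, n=self.n)
        assert np.corrcoef(y, self._sine(0.04))[0, 1] > 0.95
        assert np.allclose(y, oracle, atol=1e-10)

    def test_stopband_attenuation_at_least_20db(self):
        x = self._sine(0.2)
        y = bandpass_filter(x, 0.01, 0.08, tr=self.tr)
        in_rms = np.sqrt(np.mean(x**2))
        out_rms = np.sqrt(np.mean(y**2))
        assert 20 * np.log10(in_rms / max(out_rms, 1e-300)) >= 20

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(np.zeros(64), 0.01, 0.3, tr=2.0)

    def test_inverted_band_rejected(self):
        with pytest.raises(ValueError, match="invalid band"):
            bandpass_filter(np.zeros(64), 0.08, 0.01, tr=2.0)


class TestKendallsW:
    def test_identical_series_give_perfect_concordance(self):
        s = np.tile(np.arange(8.0), (27, 1))
        assert kendalls_w(s) == pytest.approx(1.0, abs=1e-12)

    def test_reversed_pair_gives_zero(self):
        s = np.array([[1.0, 2, 3, 4], [4.0, 3, 2, 1]])
        assert kendalls_w(s) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_random_neighborhoods(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 28))
            n = int(rng.integers(4, 21))
            s = rng.standard_normal((k, n))  # continuous: no ties
            assert kendalls_w(s) == pytest.approx(
                brute_force_kendalls_w(s), abs=1e-10
            )

    def test_range_and_affine_invariance(self, rng):
        for _ in range(20):
            s = rng.standard_normal((5, 12))
            w = kendalls_w(s)
            assert 0.0 <= w <= 1.0
            assert kendalls_w(3.7 * s + 11.0) == pytest.approx(w, abs=1e-12)


class TestRehoMap:
    def _volume(self, rng, shape=(5, 5, 5), n=12, mask=None):
        data = rng.standard_normal(shape + (n,))
        return Volume4D(data=data, mask=mask, tr=2.0)

    @pytest.mark.parametrize("neighborhood", [7, 19, 27])
    def test_matches_per_voxel_brute_force(self, rng, neighborhood):
        mask = rng.random((5, 5, 5)) > 0.2
        vol = self._volume(rng, mask=mask)
        rmap = compute_reho_map(vol, neighborhood=neighborhood)
        offsets = np.argwhere(neighborhood_footprint(neighborhood)) - 1
        for x, y, z in np.argwhere(mask):
            series = []
            for dx, dy, dz in offsets:
                xx, yy, zz = x + dx, y + dy, z + dz
                if 0 <= xx < 5 and 0 <= yy < 5 and 0 <= zz < 5 and mask[xx, yy, zz]:
                    series.append(vol.data[xx, yy, zz])
            expected = brute_force_kendalls_w(np.array(series))
            assert rmap.values[x, y, z] == pytest.approx(expected, abs=1e-10)

    def test_identical_neighborhood_series_give_one(self):
        base = np.arange(10.0)
        data = np.broadcast_to(base, (5, 5, 5, 10)).copy()
        rmap = compute_reho_map(Volume4D(data=data, tr=2.0))
        assert np.allclose(rmap.values, 1.0)

    def test_out_of_mask_is_nan_and_in_mask_in_unit_interval(self, rng):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[1:4, 1:4, 1:4] = True
        vol = self._volume(rng, mask=mask)
        rmap = compute_reho_map(vol)
        assert np.isnan(rmap.values[~mask]).all()
        inside = rmap.values[mask]
        assert ((inside >= 0) & (inside <= 1)).all()

    def test_constant_neighborhood_flagged_missing(self):
        data = np.ones((3, 3, 3, 8))
        rmap = compute_reho_map(Volume4D(data=data, tr=2.0))
        assert np.isnan(rmap.values).all()

    def test_skip_mode_drops_incomplete_neighborhoods(self, rng):
        vol = self._volume(rng)
        rmap = compute_reho_map(vol, boundary="skip")
        assert np.isnan(rmap.values[0, 0, 0])  # corner has 8 < 27 neighbors
        assert np.isfinite(rmap.values[2, 2, 2])

    def test_affine_rescaling_leaves_map_unchanged(self, rng):
        vol = self._volume(rng)
        vol2 = Volume4D(data=2.5 * vol.data + 7.0, tr=2.0)
        a = compute_reho_map(vol).values
        b = compute_reho_map(vol2).values
        assert np.allclose(a, b, atol=1e-12)


class TestSmoothMap:
    def test_constant_map_unchanged(self):
        out = smooth_map(np.full((7, 7, 7), 3.25), fwhm_mm=8, voxel_size=(3, 3, 3))
        assert np.allclose(out, 3.25, atol=1e-10)

    def test_impulse_response_is_gaussian(self):
        vol = np.zeros((21, 21, 21))
        vol[10, 10, 10] = 1.0
        out = smooth_map(vol, fwhm_mm=4, voxel_size=(2, 2, 2),
                         mask=np.ones_like(vol, dtype=bool))
        sigma_vox = 4 / (2 * np.sqrt(2 * np.log(2))) / 2.0
        d = np.arange(21) - 10
        g = np.exp(-(d**2) / (2 * sigma_vox**2))
        # along an axis through the impulse, profile is proportional to the kernel
        profile = out[:, 10, 10]
        ratio = profile[8:13] / g[8:13]
        assert np.allclose(ratio, ratio[2], rtol=1e-3)

    def test_matches_dense_explicit_kernel_convolution(self, rng):
        shape = (9, 9, 9)
        data = rng.random(shape)
        mask = rng.random(shape) > 0.15
        out = smooth_map(data, fwhm_mm=6, voxel_size=(3, 3, 3), mask=mask)
        # dense renormalized-kernel oracle
        sigma = 6 / (2 * np.sqrt(2 * np.log(2))) / 3.0
        idx = np.indices(shape)
        expected = np.full(shape, np.nan)
        for x, y, z in np.argwhere(mask):
            d2 = (idx[0] - x) ** 2 + (idx[1] - y) ** 2 + (idx[2] - z) ** 2
            w = np.exp(-d2 / (2 * sigma**2)) * mask
            expected[x, y, z] = np.sum(w * np.where(mask, data, 0)) / np.sum(w)
        assert np.allclose(out[mask], expected[mask], rtol=5e-3, atol=5e-3)


class TestRoiExtraction:
    def test_single_voxel_roi_is_verbatim(self, rng):
        data = rng.standard_normal((3, 3, 3, 6))
        labels = np.zeros((3, 3, 3), dtype=int)
        labels[1, 1, 1] = 1
        ts = extract_roi_timecourses(Volume4D(data=data, tr=2.0), Parcellation(labels))
        assert np.array_equal(ts.data[:, 0], data[1, 1, 1])

    def test_two_voxel_roi_is_mean(self, rng):
        data = rng.standard_normal((3, 3, 3, 6))
        labels = np.zeros((3, 3, 3), dtype=int)
        labels[0, 0, 0] = labels[2, 2, 2] = 1
        ts = extract_roi_timecourses(Volume4D(data=data, tr=2.0), Parcellation(labels))
        assert np.allclose(ts.data[:, 0], (data[0, 0, 0] + data[2, 2, 2]) / 2)

    def test_three_roi_phantom_matches_hand_computation(self, rng):
        data = rng.standard_normal((4, 4, 4, 5))
        labels = np.zeros((4, 4, 4), dtype=int)
        labels[0, :, :] = 1
        labels[1, :2, :] = 2
        labels[3, 3, 3] = 3
        ts = extract_roi_timecourses(Volume4D(data=data, tr=2.0), Parcellation(labels))
        for j, roi in enumerate([1, 2, 3]):
            sel = labels == roi
            assert np.allclose(ts.data[:, j], data[sel].mean(axis=0))

    def test_roi_outside_mask_reported_by_id(self, rng):
        data = rng.standard_normal((3, 3, 3, 5))
        labels = np.ones((3, 3, 3), dtype=int)
        labels[0, 0, 0] = 2
        mask = labels == 1
        with pytest.raises(ValueError, match=r"\[2\]"):
            extract_roi_timecourses(
                Volume4D(data=data, mask=mask, tr=2.0), Parcellation(labels)
            )


class TestFcMatrix:
    def test_identical_columns_correlate_to_one(self, rng):
        a = rng.standard_normal(20)
        fc = compute_fc_matrix(RoiTimecourses(np.column_stack([a, a])))
        assert fc.values[0, 1] == pytest.approx(1.0)

    def test_negated_shifted_column_correlates_to_minus_one(self, rng):
        a = rng.standard_normal(20)
        fc = compute_fc_matrix(RoiTimecourses(np.column_stack([a, -a + 3.0])))
        assert fc.values[0, 1] == pytest.approx(-1.0)

    def test_matches_hand_covariance_oracle(self):
        a = np.array([1.0, 4, 2, 6, 3, 5])
        b = np.array([2.0, 3, 1, 5, 6, 4])
        fc = compute_fc_matrix(RoiTimecourses(np.column_stack([a, b])))
        cov = np.mean((a - a.mean()) * (b - b.mean()))
        expected = cov / (a.std() * b.std())
        assert fc.values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_unit_diagonal_and_affine_invariant(self, rng):
        data = rng.standard_normal((30, 6))
        fc = compute_fc_matrix(RoiTimecourses(data))
        assert np.array_equal(fc.values, fc.values.T)
        assert np.allclose(np.diag(fc.values), 1.0)
        fc2 = compute_fc_matrix(RoiTimecourses(0.2 * data + 5.0))
        assert np.allclose(fc.values, fc2.values, atol=1e-10)

    def test_zero_variance_column_flagged_with_warning(self, rng):
        data = rng.standard_normal((10, 3))
        data[:, 1] = 2.0
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            fc = compute_fc_matrix(RoiTimecourses(data))
        assert np.isnan(fc.values[1, :]).all() and np.isnan(fc.values[:, 1]).all()
        assert np.isfinite(fc.values[0, 2])


class TestPruneAndVectorize:
    def test_threshold_semantics(self):
        values = np.array(
            [[1.0, 0.2, -0.04], [0.2, 1.0, 0.051], [-0.04, 0.051, 1.0]]
        )
        pruned = prune_fc(FcMatrix(values), threshold=0.05)
        assert pruned.values[0, 1] == 0.2
        assert pruned.values[0, 2] == 0.0
        assert pruned.values[1, 2] == 0.051

    def test_boundary_value_kept_and_just_below_dropped(self):
        values = np.eye(2)
        values[0, 1] = values[1, 0] = -0.05
        assert prune_fc(FcMatrix(values)).values[0, 1] == -0.05
        values[0, 1] = values[1, 0] = 0.049
        assert prune_fc(FcMatrix(values)).values[0, 1] == 0.0

    def test_pruning_is_idempotent_and_diagonal_untouched(self, rng):
        data = rng.standard_normal((25, 8))
        fc = compute_fc_matrix(RoiTimecourses(data))
        once = prune_fc(fc, 0.3)
        twice = prune_fc(once, 0.3)
        assert np.array_equal(once.values, twice.values)
        assert np.allclose(np.diag(once.values), 1.0)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            prune_fc(FcMatrix(np.eye(3)), threshold=-0.1)

    def test_vector_length_and_pair_ids(self):
        fc = FcMatrix(np.eye(3), roi_ids=[1, 2, 3])
        vec, ids = vectorize_fc(fc)
        assert vec.shape == (3,)
        assert ids == ["1-2", "1-3", "2-3"]

    def test_full_atlas_vector_length(self):
        m = 351
        fc = FcMatrix(np.eye(m))
        vec, _ = vectorize_fc(fc)
        assert vec.size == 61425  # m(m-1)/2

    def test_vectorize_devectorize_round_trip(self, rng):
        data = rng.standard_normal((40, 7))
        fc = compute_fc_matrix(RoiTimecourses(data))
        vec, _ = vectorize_fc(fc)
        back = devectorize_fc(vec, fc.roi_ids)
        assert np.allclose(back.values, fc.values, atol=1e-15)

    def test_asymmetric_input_rejected(self):
        values = np.eye(3)
        values[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            vectorize_fc(FcMatrix(values))


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=2, max_value=10), st.integers(min_value=0, max_value=10**6))
def test_vectorize_bijection_property(m, seed):
    rng = np.random.default_rng(seed)
    sym = rng.standard_normal((m, m))
    sym = (sym + sym.T) / 2
    np.fill_diagonal(sym, 1.0)
    fc = FcMatrix(sym)
    vec, ids = vectorize_fc(fc)
    assert len(ids) == m * (m - 1) // 2
    assert np.array_equal(devectorize_fc(vec, fc.roi_ids).values, sym)
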