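"""TIC normalization, binning, thresholding, top-K selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import smearmsi as sm
from smearmsi.preprocess import (
    PeakMatrix,
    bin_centroids,
    build_feature_matrix,
    concat_peak_matrices,
    load_peak_matrix,
    save_peak_matrix,
    select_top_k,
    threshold_filter,
    tic_normalize,
)


def spectrum(mz, inten):
    return sm.Spectrum(np.asarray(mz, float), np.asarray(inten, float))


class TestTicNormalize:
    def test_divides_by_total(self):
        out = tic_normalize(spectrum([100.0, 200.0, 300.0], [2.0, 3.0, 5.0]))
        np.testing.assert_allclose(out.intensity, [0.2, 0.3, 0.5])
        assert out.intensity.sum() == pytest.approx(1.0)

    def test_idempotent(self):
        once = tic_normalize(spectrum([100.0, 200.0], [1.0, 3.0]))
        twice = tic_normalize(once)
        np.testing.assert_allclose(twice.intensity, once.intensity)

    def test_all_zero_is_error(self):
        with pytest.raises(ValueError):
            tic_normalize(spectrum([100.0, 200.0], [0.0, 0.0]))


class TestBinCentroids:
    def test_weighted_centroid_in_shared_bin(self):
        # both points fall in [200.000, 200.020): centroid is the
        # intensity-weighted mean (1*200.003 + 3*200.015)/4 = 200.012
        bins, centroid, inten = bin_centroids(
            spectrum([200.003, 200.015], [1.0, 3.0]), 0.020, mz_low=200.0
        )
        assert bins.tolist() == [0]
        assert centroid[0] == pytest.approx(200.012, abs=1e-9)
        assert inten[0] == pytest.approx(4.0)

    def test_single_point_centroid_is_itself(self):
        _, centroid, inten = bin_centroids(spectrum([250.0137], [2.5]), 0.020, 200.0)
        assert centroid[0] == pytest.approx(250.0137)
        assert inten[0] == pytest.approx(2.5)

    def test_edge_point_goes_to_upper_bin(self):
        bins, _, _ = bin_centroids(spectrum([200.02], [1.0]), 0.020, 200.0)
        assert bins.tolist() == [1]

    def test_conserves_total_intensity(self):
        rng = np.random.default_rng(0)
        mz = np.sort(rng.uniform(200, 600, 500))
        inten = rng.exponential(1.0, 500)
        _, _, binned = bin_centroids(spectrum(mz, inten), 0.020, 200.0)
        assert binned.sum() == pytest.approx(inten.sum(), rel=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(
        data=st.lists(
            st.tuples(st.floats(200.001, 599.99), st.floats(0.0, 10.0)),
            min_size=1, max_size=100,
        )
    )
    def test_matches_brute_force_oracle(self, data):
        mz = np.sort(np.unique([m for m, _ in data]))
        inten = np.array([dict(data)[m] for m in mz])
        sp = spectrum(mz, inten)
        bins, centroid, binned = bin_centroids(sp, 0.020, 200.0)
        # O(n*bins) reference: assign each point independently
        ref: dict[int, list] = {}
        for m, it in zip(mz, inten):
            k = int(np.floor((m - 200.0) / 0.020))
            ref.setdefault(k, []).append((m, it))
        assert bins.tolist() == sorted(ref)
        for k, c, s in zip(bins, centroid, binned):
            ms = np.array([m for m, _ in ref[k]])
            its = np.array([it for _, it in ref[k]])
            assert s == pytest.approx(its.sum(), abs=1e-12)
            if its.sum() > 0:
                assert c == pytest.approx((ms * its).sum() / its.sum(), abs=1e-9)


class TestThresholdAndTopK:
    def test_strict_inequality_at_cutoff(self):
        vals = np.array([1.0, 1.01, 0.5])
        keep = threshold_filter(vals, reference_max=1000.0, fraction=0.001)
        assert keep.tolist() == [False, True, False]

    def test_fraction_zero_keeps_all_positive(self):
        vals = np.array([0.1, 5.0, 2.0])
        assert threshold_filter(vals, 1000.0, 0.0).all()

    def test_monotone_in_fraction(self):
        rng = np.random.default_rng(1)
        vals = rng.exponential(1.0, 300)
        counts = [threshold_filter(vals, vals.max(), f).sum()
                  for f in (0.0, 0.001, 0.01, 0.1, 0.5)]
        assert counts == sorted(counts, reverse=True)

    def _matrix(self, means):
        means = np.asarray(means, float)
        mz = 200.0 + np.arange(means.size) * 0.02 + 0.01
        return PeakMatrix(
            mz=mz, bin_index=np.arange(means.size),
            matrix=np.vstack([means, means]),
            pixel_indices=np.array([0, 1]), provenance={},
        )

    def test_top_k_keeps_k_most_intense(self):
        rng = np.random.default_rng(2)
        pm = self._matrix(rng.uniform(0.1, 1.0, 800))
        out = select_top_k(pm, 500)
        assert out.n_features == 500
        dropped = set(pm.bin_index) - set(out.bin_index)
        kept_min = pm.matrix.mean(axis=0)[np.isin(pm.bin_index, out.bin_index)].min()
        dropped_max = pm.matrix.mean(axis=0)[np.isin(pm.bin_index, list(dropped))].max()
        assert kept_min >= dropped_max

    def test_top_k_short_input_passthrough(self):
        pm = self._matrix(np.linspace(1, 2, 120))
        assert select_top_k(pm, 500).n_features == 120

    def test_tie_broken_toward_lower_mz(self):
        pm = self._matrix([1.0, 2.0, 2.0, 1.0])
        out = select_top_k(pm, 3)
        # both 2.0-bins kept, then the tie between the two 1.0-bins goes
        # to the lower m/z
        assert out.bin_index.tolist() == [0, 1, 2]


class TestBuildFeatureMatrix:
    def test_threshold_500_survivors_exact(self):
        """A constructed dataset with 800 bins, 300 of them at or below
        0.1% of the reference maximum, keeps exactly 500 bins."""
        n = 800
        axis = 200.0 + np.arange(n) * 0.02 + 0.01
        big = np.full(500, 1.0)
        small = np.full(300, 0.0005)  # below 0.1% of max of the mean spectrum
        inten = np.concatenate([big, small])
        rng = np.random.default_rng(3)
        inten = inten[rng.permutation(n)]
        spectra = [sm.Spectrum(axis, inten) for _ in range(4)]
        ds = sm.MSIDataset(2, 2, 8.0, 7.0, -1, "9AA", "D0", (200.0, 900.0),
                           spectra, uniform_axis=axis)
        pm = build_feature_matrix(ds, top_k=800)
        assert pm.n_features == 500

    def test_marker_bin_centroid(self, small_smear):
        ds, _, _ = small_smear
        pm = build_feature_matrix(ds)
        atp = 505.988
        k = int(np.floor((atp - 200.0) / 0.020))
        assert k in pm.bin_index
        centroid = pm.mz[pm.bin_index.tolist().index(k)]
        assert centroid == pytest.approx(atp, abs=0.005)

    def test_row_sums_bounded_by_one(self, small_smear):
        ds, _, _ = small_smear
        pm = build_feature_matrix(ds)
        assert pm.matrix.min() >= 0
        assert pm.matrix.sum(axis=1).max() <= 1 + 1e-9

    def test_all_zero_pixels_excluded(self):
        axis = np.array([250.0, 250.01])
        spectra = [sm.Spectrum(axis, np.array([1.0, 2.0])) for _ in range(3)]
        spectra.append(sm.Spectrum(axis, np.array([0.0, 0.0])))
        ds = sm.MSIDataset(2, 2, 8.0, 7.0, -1, "9AA", "D0", (200.0, 600.0),
                           spectra, uniform_axis=axis)
        pm = build_feature_matrix(ds)
        assert pm.pixel_indices.tolist() == [0, 1, 2]
        assert pm.provenance["excluded_pixels"] == [3]

    def test_every_pixel_empty_is_error(self):
        axis = np.array([250.0])
        spectra = [sm.Spectrum(axis, np.array([0.0])) for _ in range(4)]
        ds = sm.MSIDataset(2, 2, 8.0, 7.0, -1, "9AA", "D0", (200.0, 600.0),
                           spectra, uniform_axis=axis)
        with pytest.raises(ValueError):
            build_feature_matrix(ds)

    def test_uniform_and_per_pixel_paths_agree(self, tiny_dataset):
        pm_fast = build_feature_matrix(tiny_dataset)
        slow = sm.MSIDataset(
            tiny_dataset.n_x, tiny_dataset.n_y, tiny_dataset.pitch_x,
            tiny_dataset.pitch_y, tiny_dataset.polarity, tiny_dataset.matrix_label,
            tiny_dataset.setting_label, tiny_dataset.mz_range,
            tiny_dataset.spectra, uniform_axis=None,
        )
        pm_slow = build_feature_matrix(slow)
        np.testing.assert_allclose(pm_fast.mz, pm_slow.mz, atol=1e-12)
        np.testing.assert_allclose(pm_fast.matrix, pm_slow.matrix, atol=1e-12)

    def test_two_ranges_concatenate(self):
        def make(lo, hi, n):
            axis = lo + 5 + np.arange(n) * 0.5
            spectra = [sm.Spectrum(axis, np.ones(n)) for _ in range(4)]
            return sm.MSIDataset(2, 2, 8.0, 7.0, -1, "9AA", "D0", (lo, hi),
                                 spectra, uniform_axis=axis)
        a = build_feature_matrix(make(200.0, 600.0, 30))
        b = build_feature_matrix(make(600.0, 900.0, 20))
        both = concat_peak_matrices(a, b)
        assert both.n_features == a.n_features + b.n_features
        assert np.all(np.diff(both.mz) > 0)

    def test_save_load_round_trip(self, small_smear, tmp_path):
        ds, _, _ = small_smear
        pm = build_feature_matrix(ds, top_k=50)
        path = tmp_path / "peaks.csv"
        save_peak_matrix(pm, path)
        back = load_peak_matrix(path)
        assert back.provenance["bin_width"] == pm.provenance["bin_width"]
        np.testing.assert_array_equal(back.bin_index, pm.bin_index)
        np.testing.assert_allclose(back.matrix, pm.matrix, rtol=1e-8)
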