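"""Generator behavior: determinism, geometry, noise model, ground truth."""

import numpy as np
import pytest

import smearmsi as sm
from smearmsi.synthetic_smear import (
    PEAK_SHAPE_SUM,
    SimulationError,
    _build_peak_panel,
    _place_cells,
)


def window_mean(dataset, target, tol=0.025, mask=None):
    """Mean raw intensity in a ±tol window, optionally over a pixel mask."""
    axis = dataset.uniform_axis
    cols = (axis >= target - tol) & (axis <= target + tol)
    mat = np.vstack([sp.intensity for sp in dataset.spectra])
    vals = mat[:, cols].sum(axis=1)
    return vals if mask is None else vals[mask]


class TestDeterminismAndStructure:
    def test_same_seed_bit_identical(self):
        a, _, _ = sm.generate_smear(sm.SmearSimConfig(n_x=16, n_y=16, seed=99))
        b, _, _ = sm.generate_smear(sm.SmearSimConfig(n_x=16, n_y=16, seed=99))
        np.testing.assert_array_equal(a.uniform_axis, b.uniform_axis)
        for sa, sb in zip(a.spectra, b.spectra):
            np.testing.assert_array_equal(sa.intensity, sb.intensity)

    def test_roi_design_counts(self, small_smear):
        _, rois, _ = small_smear
        labels = [r.label for r in rois]
        assert labels.count("RBC") == 5
        assert labels.count("WBC") == 1
        assert labels.count("plasma") == 3

    def test_roi_center_labels_match_pixel_labels(self, small_smear):
        ds, rois, truth = small_smear
        for roi in rois:
            i = int(roi.center[0] / ds.pitch_x)
            j = int(roi.center[1] / ds.pitch_y)
            assert truth.labels[j, i] == roi.label

    def test_truth_enriched_within_marker_panel(self, small_smear):
        _, _, truth = small_smear
        cfg = sm.SmearSimConfig(n_x=24, n_y=24, seed=11)
        panel = {p.mz for p in cfg.resolved_markers() + cfg.resolved_plasma_peaks()}
        assert {mz for mz, _, _ in truth.enriched} <= panel
        directions = {(cls, d) for _, cls, d in truth.enriched}
        assert ("RBC", "up") in directions and ("RBC", "down") in directions

    def test_placement_error_when_grid_too_small(self):
        cfg = sm.SmearSimConfig(n_x=6, n_y=6, n_rbc=200, seed=0)
        with pytest.raises(SimulationError):
            sm.generate_smear(cfg)

    def test_cells_do_not_overlap(self):
        cfg = sm.SmearSimConfig(n_x=32, n_y=32, seed=4)
        rng = np.random.default_rng(0)
        _, cells = _place_cells(cfg, rng)
        for a in range(len(cells)):
            for b in range(a + 1, len(cells)):
                (_, (x1, y1), r1), (_, (x2, y2), r2) = cells[a], cells[b]
                assert np.hypot(x1 - x2, y1 - y2) >= r1 + r2


class TestNoiseModel:
    def test_null_mode_strips_enrichment(self):
        cfg = sm.SmearSimConfig(null_mode=True)
        assert all(not p.enrichment for p in cfg.resolved_markers())
        assert all(not p.enrichment for p in cfg.resolved_plasma_peaks())
        assert cfg.effective_donor_sigma == 0.0

    def test_marker_enrichment_ratio_matches_model(self):
        """RBC/plasma intensity ratio in the ATP window equals the model
        expectation (enrichment diluted by the additive baseline)."""
        cfg = sm.SmearSimConfig(n_x=32, n_y=32, seed=21)
        ds, _, truth = sm.generate_smear(cfg)
        flat = truth.labels.ravel()
        atp = cfg.resolved_markers()[0]
        rbc = window_mean(ds, atp.mz, mask=flat == "RBC")
        plasma = window_mean(ds, atp.mz, mask=flat == "plasma")
        # model expectation: windows hold amplitude*shape_sum*E[tic] plus
        # n_points * half-normal baseline mean
        axis = ds.uniform_axis
        n_pts = int(((axis >= atp.mz - 0.025) & (axis <= atp.mz + 0.025)).sum())
        tic_mean = np.exp(cfg.tic_sigma**2 / 2)
        base = n_pts * cfg.baseline_sigma * np.sqrt(2 / np.pi)
        enrich = atp.enrichment["RBC"]
        expected = (enrich * atp.amplitude * PEAK_SHAPE_SUM * tic_mean + base) / (
            atp.amplitude * PEAK_SHAPE_SUM * tic_mean + base
        )
        ratio = rbc.mean() / plasma.mean()
        se = ratio * np.sqrt(
            rbc.std(ddof=1) ** 2 / (rbc.mean() ** 2 * rbc.size)
            + plasma.std(ddof=1) ** 2 / (plasma.mean() ** 2 * plasma.size)
        )
        assert abs(ratio - expected) <= 3 * se

    def test_expected_tic_conservation(self):
        """Mean pixel TIC equals the configured total peak area times the
        log-normal TIC factor mean, plus the baseline mean, within 3 SE.

        The configured panel is recovered by replaying the generator's
        seeded RNG stream (placement, ROI selection, panel) and summing
        the stated amplitudes — an oracle independent of the spectra.
        """
        from smearmsi.synthetic_smear import _select_rois

        cfg = sm.SmearSimConfig(n_x=32, n_y=32, null_mode=True, seed=8)
        ds, _, _ = sm.generate_smear(cfg)

        rng = np.random.default_rng(cfg.seed)
        labels, cells = _place_cells(cfg, rng)
        _select_rois(cfg, labels, cells, rng, "donor01", "smear01")
        peaks = _build_peak_panel(cfg, rng)
        amp_total = sum(p.amplitude for p in peaks)  # null mode: all class factors 1

        tics = np.array([sp.tic for sp in ds.spectra])
        n_pts = ds.uniform_axis.size
        tic_mean = np.exp(cfg.tic_sigma**2 / 2)
        expected = amp_total * PEAK_SHAPE_SUM * tic_mean + n_pts * cfg.baseline_sigma * np.sqrt(2 / np.pi)
        se = tics.std(ddof=1) / np.sqrt(tics.size)
        assert abs(tics.mean() - expected) <= 3 * se


class TestStudy:
    def test_study_shape(self, small_study):
        assert len(small_study) == 6
        for smear in small_study:
            labels = [r.label for r in smear.roi_set]
            assert (labels.count("RBC"), labels.count("WBC"), labels.count("plasma")) == (5, 1, 3)
            assert len(smear.datasets) == 1

    def test_single_donor_rejected(self):
        with pytest.raises(ValueError):
            sm.generate_study(sm.SmearSimConfig(n_x=16, n_y=16, seed=1), n_donors=1)

    def test_shared_peak_panel_across_donors(self, small_study):
        axes = [s.datasets[0].uniform_axis for s in small_study]
        for a in axes[1:]:
            np.testing.assert_array_equal(a, axes[0])

    def test_zero_donor_sigma_equalizes_donor_means(self):
        cfg = sm.SmearSimConfig(n_x=24, n_y=24, donor_sigma=0.0, null_mode=True, seed=13)
        study = sm.generate_study(cfg, n_donors=4)
        atp_means = [window_mean(s.datasets[0], 505.988).mean() for s in study]
        spread = np.std(atp_means) / np.mean(atp_means)
        assert spread < 0.05  # only pixel noise left across donors

    def test_two_ranges_share_layout(self):
        cfg = sm.SmearSimConfig(n_x=16, n_y=16, seed=3)
        study = sm.generate_study(cfg, n_donors=2, mz_ranges=[(200.0, 600.0), (600.0, 900.0)])
        for smear in study:
            assert len(smear.datasets) == 2
            assert smear.datasets[0].mz_range == (200.0, 600.0)
            assert smear.datasets[1].mz_range == (600.0, 900.0)


class TestPeakPanel:
    def test_panel_respects_range_and_spacing(self):
        cfg = sm.SmearSimConfig(mz_range=(200.0, 600.0), seed=2)
        peaks = _build_peak_panel(cfg, np.random.default_rng(2))
        mzs = np.sort([p.mz for p in peaks])
        assert mzs[0] >= 200.0 and mzs[-1] <= 600.0
        assert np.min(np.diff(mzs)) > 6 * cfg.peak_sigma  # supports disjoint
        assert len(peaks) > 500  # enough candidates for the top-K cap to bind
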