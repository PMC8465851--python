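"""TIC normalization, peak picking on the mean spectrum, matrix extraction."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

from msimarker.core import Feature, MSIDataset, Spectrum
from msimarker.preprocess import (PreprocessConfig, build_peak_matrix,
                                  mean_spectrum, pick_peaks, tic_normalize)


def gaussian_peak(axis, center, height, sigma=0.05):
    return height * np.exp(-0.5 * ((axis - center) / sigma) ** 2)


def single_section(axis, rows, region="media"):
    rows = np.atleast_2d(rows)
    n = rows.shape[0]
    coords = np.column_stack([np.arange(n), np.zeros(n, dtype=int)])
    return MSIDataset.from_grid(axis, rows, coords, "s1", "TAA", [region] * n)


class TestTicNormalize:
    def test_proportions(self):
        out = tic_normalize(Spectrum([100.0, 200.0], [1.0, 3.0]), target=1.0)
        assert out.intensity == pytest.approx([0.25, 0.75])
        assert out.mz == pytest.approx([100.0, 200.0])

    def test_idempotent_at_fixed_target(self):
        s = Spectrum(np.arange(5.0) + 1, [0.1, 2.0, 0.0, 5.0, 1.3])
        once = tic_normalize(s, target=7.0)
        twice = tic_normalize(once, target=7.0)
        assert twice.intensity == pytest.approx(once.intensity, rel=1e-12)

    def test_target_sum_reached_within_tolerance(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            s = Spectrum(np.sort(rng.uniform(600, 3200, 50)), rng.uniform(0, 10, 50))
            out = tic_normalize(s, target=100.0)
            assert out.tic == pytest.approx(100.0, rel=1e-9)

    def test_conserves_relative_peak_ratios(self):
        s = Spectrum([1.0, 2.0, 3.0], [2.0, 4.0, 8.0])
        out = tic_normalize(s, target=42.0)
        assert out.intensity[1] / out.intensity[0] == pytest.approx(2.0)
        assert out.intensity[2] / out.intensity[1] == pytest.approx(2.0)

    def test_zero_spectrum_names_pixel(self):
        with pytest.raises(ValueError, match="p7"):
            tic_normalize(Spectrum([1.0, 2.0], [0.0, 0.0]), pixel="p7")


class TestPickPeaks:
    axis = np.arange(999.0, 1002.0, 0.01)

    def test_separated_peaks_yield_two_features(self):
        row = gaussian_peak(self.axis, 1000.0, 5.0) + gaussian_peak(self.axis, 1000.5, 3.0)
        feats = pick_peaks([single_section(self.axis, row)])
        assert len(feats) == 2
        assert [f.center_mz for f in feats] == pytest.approx([1000.0, 1000.5], abs=0.02)

    def test_peaks_closer_than_interval_merge_to_one(self):
        row = gaussian_peak(self.axis, 1000.0, 5.0) + gaussian_peak(self.axis, 1000.2, 3.0)
        feats = pick_peaks([single_section(self.axis, row)])
        assert len(feats) == 1
        assert feats[0].width == pytest.approx(0.3)

    def test_apexes_match_brute_force_maxima_of_smoothed_mean(self):
        rng = np.random.default_rng(4)
        rows = np.array([
            gaussian_peak(self.axis, 1000.0, 5.0) + gaussian_peak(self.axis, 1001.2, 2.0)
            + rng.uniform(0, 0.001, self.axis.size)
            for _ in range(3)
        ])
        ds = single_section(self.axis, rows)
        cfg = PreprocessConfig()
        feats = pick_peaks([ds], cfg)
        mean = mean_spectrum([ds], cfg).intensity
        sm = gaussian_filter1d(mean, cfg.smoothing_sigma)
        maxima = [
            self.axis[i] for i in range(1, sm.size - 1)
            if sm[i] > sm[i - 1] and sm[i] >= sm[i + 1]
            and sm[i] > 0.1 * sm.max()
        ]
        assert [f.center_mz for f in feats] == pytest.approx(maxima, abs=1e-9)

    def test_flat_spectrum_yields_nothing(self):
        assert pick_peaks([single_section(self.axis, np.ones(self.axis.size))]) == []

    def test_intervals_have_exact_width_and_no_overlap(self):
        rng = np.random.default_rng(8)
        row = sum(gaussian_peak(self.axis, c, h) for c, h in
                  zip(rng.uniform(999.3, 1001.7, 8), rng.uniform(1, 5, 8)))
        feats = pick_peaks([single_section(self.axis, row)], PreprocessConfig(interval_width=0.3))
        assert all(f.width == pytest.approx(0.3) for f in feats)
        for f, g in zip(feats, feats[1:]):
            assert f.high <= g.low + 1e-12


class TestBuildPeakMatrix:
    def test_single_peak_height(self):
        axis = np.arange(999.0, 1001.0, 0.01)
        row = gaussian_peak(axis, 1000.0, 5.0)
        ds = single_section(axis, row)
        pm = build_peak_matrix([ds], [Feature(1000.0, 0.15)])
        normalized_height = 5.0 / row.sum()
        assert pm.intensity[0, 0] == pytest.approx(normalized_height, rel=1e-12)

    def test_matches_brute_force_interval_max(self):
        rng = np.random.default_rng(6)
        axis = np.sort(rng.uniform(600, 700, 400))
        rows = rng.uniform(0, 5, size=(4, 400))
        ds = single_section(axis, rows)
        feats = [Feature(c, 0.3) for c in (610.0, 650.0, 690.0)]
        pm = build_peak_matrix([ds], feats)
        norm = rows / rows.sum(axis=1, keepdims=True)
        checked = 0
        for i in range(4):
            for j, f in enumerate(feats):
                inside = [norm[i, k] for k in range(400) if f.low <= axis[k] <= f.high]
                expected = max(inside) if inside else 0.0
                assert pm.intensity[i, j] == pytest.approx(expected, rel=1e-12)
                checked += bool(inside)
        assert checked > 0

    def test_row_order_follows_spectrum_order(self):
        axis = np.arange(999.0, 1001.0, 0.01)
        rows = np.array([gaussian_peak(axis, 1000.0, h) for h in (1.0, 2.0, 3.0)])
        ds = single_section(axis, rows)
        perm = [2, 0, 1]
        ds_perm = MSIDataset.from_grid(
            axis, rows[perm],
            np.column_stack([np.array(perm), np.zeros(3, int)]),
            "s1", "TAA", ["media"] * 3,
        )
        feats = [Feature(1000.0, 0.15)]
        a = build_peak_matrix([ds], feats).intensity
        b = build_peak_matrix([ds_perm], feats).intensity
        assert b == pytest.approx(a[perm])

    def test_empty_interval_warns_and_zeroes(self):
        axis = np.arange(999.0, 1001.0, 0.01)
        ds = single_section(axis, gaussian_peak(axis, 1000.0, 5.0))
        with pytest.warns(UserWarning, match="no axis points"):
            pm = build_peak_matrix([ds], [Feature(900.0, 0.15), Feature(1000.0, 0.15)])
        assert pm.intensity[0, 0] == 0.0
        assert pm.intensity[0, 1] > 0

    def test_stable_under_axis_refinement(self):
        """Synthetic Gaussian peak entries move <1% under a finer axis."""
        coarse = np.arange(999.0, 1001.0, 0.01)
        fine = np.arange(999.0, 1001.0, 0.002)
        feats = [Feature(1000.0, 0.15)]
        val = {}
        for name, axis in (("coarse", coarse), ("fine", fine)):
            row = gaussian_peak(axis, 1000.0, 5.0) + 0.01
            pm = build_peak_matrix([single_section(axis, row)], feats)
            # undo the axis-density dependence of the TIC by comparing the
            # ratio of the entry to the normalized baseline level
            val[name] = pm.intensity[0, 0] / (0.01 / row.sum())
        assert val["fine"] == pytest.approx(val["coarse"], rel=0.01)
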