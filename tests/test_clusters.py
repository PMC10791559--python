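import numpy as np
import pytest

from myoquant.clusters import (cluster_stats, icd_cluster_profile,
                               occupancy_pct, segment_clusters)
from myoquant.imgeo import ImageStack, RegionMask


def flood_fill_components(fg: np.ndarray) -> np.ndarray:
    """Independent 8-connected labeling by breadth-first flood fill."""
    labels = np.zeros(fg.shape, dtype=int)
    next_label = 0
    for sy, sx in zip(*np.nonzero(fg)):
        if labels[sy, sx]:
            continue
        next_label += 1
        stack = [(sy, sx)]
        labels[sy, sx] = next_label
        while stack:
            y, x = stack.pop()
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    yy, xx = y + dy, x + dx
                    if (0 <= yy < fg.shape[0] and 0 <= xx < fg.shape[1]
                            and fg[yy, xx] and not labels[yy, xx]):
                        labels[yy, xx] = next_label
                        stack.append((yy, xx))
    return labels


class TestSegmentClusters:
    def test_blank_image_gives_no_clusters(self):
        roi = RegionMask(np.ones((50, 50), bool), 0.05)
        with pytest.warns(UserWarning):
            cs = segment_clusters(np.zeros((50, 50)), roi, threshold_method=1.0)
        assert cs.n_clusters == 0
        assert cluster_stats(cs).density_pct == 0.0

    def test_single_square_cluster_arithmetic(self):
        # 8x8 px square at 50 nm/pixel inside a 100x100 ROI
        img = np.zeros((100, 100))
        img[10:18, 20:28] = 100.0
        roi = RegionMask(np.ones((100, 100), bool), 0.05)
        cs = segment_clusters(img, roi, threshold_method="otsu")
        st = cluster_stats(cs)
        assert st.n_clusters == 1
        assert st.mean_size_um2 == pytest.approx(0.16)
        assert st.density_pct == pytest.approx(0.64)

    def test_labels_match_flood_fill_oracle(self, rng):
        img = np.zeros((80, 80))
        for _ in range(25):
            cy, cx = rng.integers(5, 75, 2)
            r = rng.integers(1, 4)
            yy, xx = np.ogrid[-5:6, -5:6]
            disk = yy**2 + xx**2 <= r**2
            img[cy - 5:cy + 6, cx - 5:cx + 6][disk] = 100.0
        roi = RegionMask(np.ones((80, 80), bool), 0.05)
        cs = segment_clusters(img, roi, threshold_method=50.0, min_size_px=1)
        oracle = flood_fill_components(img >= 50.0)
        assert cs.n_clusters == oracle.max()
        # identical partitions up to label permutation
        for lab in range(1, oracle.max() + 1):
            sel = oracle == lab
            assert len(np.unique(cs.label_map[sel])) == 1
            assert (cs.label_map[sel] > 0).all()

    def test_min_size_monotone(self, rng):
        img = (rng.uniform(size=(60, 60)) > 0.7) * 100.0
        roi = RegionMask(np.ones((60, 60), bool), 0.05)
        counts = [segment_clusters(img, roi, 50.0, ms).n_clusters
                  for ms in (1, 2, 4, 8)]
        assert counts == sorted(counts, reverse=True)

    def test_density_invariant_under_intensity_rescale(self, rng):
        img = np.zeros((60, 60))
        img[10:20, 10:20] = 80.0
        img += rng.uniform(0, 5, size=img.shape)
        roi = RegionMask(np.ones((60, 60), bool), 0.05)
        d1 = cluster_stats(segment_clusters(img, roi, "otsu")).density_pct
        d2 = cluster_stats(segment_clusters(img * 3.7, roi, "otsu")).density_pct
        assert d1 == pytest.approx(d2)

    def test_total_cluster_area_bounded_by_roi(self, clean_phantom):
        stack, truth = clean_phantom
        surf = stack.channel("target")[truth.surface_z]
        cs = segment_clusters(surf, truth.cell_mask)
        assert cs.areas_um2.sum() <= truth.cell_mask.area_um2


class TestClusterStats:
    def test_mean_size_and_background_subtraction(self):
        img = np.zeros((100, 100))
        img[0:8, 0:8] = 15.0        # 0.16 µm² at 50 nm
        img[50:58, 50:66] = 15.0    # 0.32 µm²
        roi = RegionMask(np.ones((100, 100), bool), 0.05)
        cs = segment_clusters(img, roi, threshold_method=10.0)
        st = cluster_stats(cs, background=5.0)
        assert st.mean_size_um2 == pytest.approx(0.24)
        assert st.mean_intensity == pytest.approx(10.0)
        assert st.mean_intensity_raw == pytest.approx(15.0)

    def test_negative_background_rejected(self, clean_phantom):
        stack, truth = clean_phantom
        cs = segment_clusters(stack.channel("target")[truth.surface_z],
                              truth.cell_mask)
        with pytest.raises(ValueError):
            cluster_stats(cs, background=-1.0)

    def test_accumulation_oracle(self, rng):
        img = rng.uniform(0, 100, size=(60, 60))
        roi = RegionMask(np.ones((60, 60), bool), 0.05)
        cs = segment_clusters(img, roi, threshold_method=60.0, min_size_px=1)
        st = cluster_stats(cs)
        fg = img >= 60.0
        assert st.density_pct == pytest.approx(100 * fg.sum() / roi.n_pixels)
        assert st.mean_intensity_raw == pytest.approx(img[fg].mean())


class TestOccupancy:
    def test_blank_and_saturated(self):
        region = RegionMask(np.ones((40, 40), bool), 0.1)
        with pytest.warns(UserWarning):
            assert occupancy_pct(np.zeros((40, 40)), region,
                                 threshold_method=1.0) == 0.0
        with pytest.warns(UserWarning):
            assert occupancy_pct(np.full((40, 40), 9.0), region,
                                 threshold_method=1.0,
                                 min_size_px=1) == 100.0

    def test_consistent_with_cluster_stats(self, clean_phantom):
        stack, truth = clean_phantom
        surf = stack.channel("target")[truth.surface_z]
        d1 = occupancy_pct(surf, truth.cell_mask)
        cs = segment_clusters(surf, truth.cell_mask)
        assert d1 == cluster_stats(cs).density_pct


class TestIcdClusterProfile:
    @staticmethod
    def _icd_stack(with_clusters: bool):
        # marker band at x indices 40..59, with target disks inside
        vox = np.zeros((2, 30, 40, 100))
        vox[1, 5:25, 5:35, 40:60] = 100.0
        if with_clusters:
            for zc, yc in ((10, 12), (18, 25)):
                vox[0, zc - 2:zc + 2, yc - 2:yc + 2, 40:60] = 200.0
        return ImageStack(vox, 0.05, 0.05, ["target", "icd_marker"])

    def test_no_target_clusters_gives_zero_density(self):
        stack = self._icd_stack(with_clusters=False)
        with pytest.warns(UserWarning):
            out = icd_cluster_profile(stack, "icd_marker", "target",
                                      [2.25], threshold_method=50.0)
        assert out[0].density_pct == 0.0

    def test_planted_clusters_recovered_exactly(self):
        stack = self._icd_stack(with_clusters=True)
        out = icd_cluster_profile(stack, "icd_marker", "target",
                                  [2.25, 2.75], threshold_method=150.0)
        px_area = 0.05 * 0.05
        roi_px = 20 * 30
        expect_density = 100 * (2 * 16) / roi_px
        for st in out:
            assert st.density_pct == pytest.approx(expect_density)
            assert st.n_clusters == 2
            assert st.mean_size_um2 == pytest.approx(16 * px_area)

    def test_positions_without_marker_reported_missing(self):
        stack = self._icd_stack(with_clusters=True)
        out = icd_cluster_profile(stack, "icd_marker", "target", [0.25],
                                  threshold_method=50.0)
        assert out == [None]
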