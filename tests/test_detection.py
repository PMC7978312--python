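"""Detection stages against independent oracles and constructed fixtures."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from punctapipe import (ChannelImage, DetectionParams, ProcessTraces,
                        binarize, component_distance, detect_puncta,
                        label_components, match_to_ground_truth,
                        normalize_image, otsu_threshold)
from punctapipe.io import point_segment_distance

from conftest import straight_trace


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def flood_fill_labels(mask):
    """Brute-force 8-connected labeling by BFS in raster order."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    nxt = 0
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if not mask[r0, c0] or labels[r0, c0]:
                continue
            nxt += 1
            stack = [(r0, c0)]
            labels[r0, c0] = nxt
            while stack:
                r, c = stack.pop()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]
                                and mask[rr, cc] and not labels[rr, cc]):
                            labels[rr, cc] = nxt
                            stack.append((rr, cc))
    return labels


def brute_force_min_distance(pixels, polylines, pixel_size):
    """Scalar pixel-by-pixel, segment-by-segment distance scan."""
    best = np.inf
    for (r, c) in pixels:
        px = np.array([(c + 0.5) * pixel_size, (r + 0.5) * pixel_size])
        for poly in polylines:
            for a, b in zip(poly[:-1], poly[1:]):
                ab = b - a
                denom = float(ab @ ab)
                t = 0.0 if denom == 0 else float(np.clip((px - a) @ ab / denom,
                                                         0.0, 1.0))
                best = min(best, float(np.linalg.norm(px - (a + t * ab))))
    return best


def brute_force_otsu(pixels):
    """Try every integer threshold; maximize inter-class variance directly."""
    arr = np.asarray(pixels, dtype=float).ravel()
    bins = np.clip(arr.astype(int), 0, 255)
    best_t, best_v = 0, -1.0
    for t in range(256):
        lo, hi = bins[bins <= t], bins[bins > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / bins.size, hi.size / bins.size
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return best_t


# ---------------------------------------------------------------------------
# normalize
# ---------------------------------------------------------------------------

class TestNormalize:
    def test_linear_map(self):
        img = ChannelImage(np.array([[10.0, 20.0], [15.0, 10.0]]), 0.1)
        out = normalize_image(img)
        np.testing.assert_allclose(out.pixels,
                                   [[0.0, 255.0], [127.5, 0.0]])

    def test_constant_maps_to_zero(self):
        img = ChannelImage(np.full((4, 4), 42.0), 0.1)
        assert not normalize_image(img).pixels.any()

    def test_idempotent_and_nondestructive(self):
        rng = np.random.default_rng(1)
        arr = rng.uniform(3, 900, (16, 16))
        img = ChannelImage(arr.copy(), 0.1)
        once = normalize_image(img)
        twice = normalize_image(once)
        np.testing.assert_allclose(twice.pixels, once.pixels, atol=1e-10)
        np.testing.assert_array_equal(img.pixels, arr)  # input untouched


# ---------------------------------------------------------------------------
# binarize / threshold
# ---------------------------------------------------------------------------

class TestBinarize:
    def test_all_zero_image_empty_mask(self):
        img = ChannelImage(np.zeros((8, 8)), 0.1)
        params = DetectionParams(threshold_mode="fixed", fixed_threshold=0.0)
        assert not binarize(img, params).any()

    def test_fixed_threshold_selects_bright_pixels(self):
        arr = np.full((6, 6), 50.0)
        arr[2:4, 2:4] = 150.0
        img = ChannelImage(arr, 0.1)
        params = DetectionParams(threshold_mode="fixed", fixed_threshold=100.0)
        mask = binarize(img, params)
        np.testing.assert_array_equal(mask, arr == 150.0)

    def test_fixed_threshold_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 255\]"):
            DetectionParams(threshold_mode="fixed", fixed_threshold=300.0)

    def test_auto_threshold_separates_bimodal_histogram(self):
        rng = np.random.default_rng(0)
        arr = np.concatenate([rng.normal(30, 8, 3000),
                              rng.normal(200, 12, 1500)])
        arr = np.clip(arr, 0, 255).reshape(90, 50)
        t = otsu_threshold(arr)
        assert 50 < t < 180
        assert t == brute_force_otsu(arr)

    @pytest.mark.parametrize("seed", range(10))
    def test_auto_threshold_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.uniform(0, 255, (24, 24))
        assert otsu_threshold(arr) == brute_force_otsu(arr)


# ---------------------------------------------------------------------------
# connected components
# ---------------------------------------------------------------------------

class TestLabelComponents:
    def test_diagonal_pixels_one_component(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        _, comps = label_components(mask)
        assert len(comps) == 1

    def test_separated_pixels_two_components(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 0] = mask[1, 2] = True
        _, comps = label_components(mask)
        assert len(comps) == 2

    def test_matches_flood_fill_oracle_on_random_masks(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            mask = rng.uniform(size=(32, 32)) < rng.uniform(0.2, 0.7)
            labels, comps = label_components(mask)
            oracle = flood_fill_labels(mask)
            np.testing.assert_array_equal(labels, oracle)
            assert len(comps) == oracle.max()

    def test_components_partition_foreground(self):
        rng = np.random.default_rng(3)
        mask = rng.uniform(size=(40, 40)) < 0.4
        _, comps = label_components(mask)
        total = sum(len(c) for c in comps)
        assert total == int(mask.sum())


# ---------------------------------------------------------------------------
# component-to-process distance
# ---------------------------------------------------------------------------

class TestComponentDistance:
    def test_component_on_polyline_vertex(self):
        tr = straight_trace(10.0, y_um=5.05, x0_um=2.0)
        # pixel (50, 30) centre = (3.05, 5.05) lies on the line
        d, pid = component_distance(np.array([[50, 30]]), tr, 0.1)
        assert d == pytest.approx(0.0, abs=1e-12)
        assert pid == 0

    def test_known_offset(self):
        tr = straight_trace(10.0, y_um=5.05, x0_um=2.0)
        d, _ = component_distance(np.array([[65, 30]]), tr, 0.1)
        assert d == pytest.approx(1.5, abs=1e-12)

    def test_empty_component_rejected(self):
        tr = straight_trace(5.0)
        with pytest.raises(ValueError, match="empty"):
            component_distance(np.empty((0, 2)), tr, 0.1)

    def test_no_traces_infinite_distance(self):
        tr = ProcessTraces([], 0.1, (32, 32))
        d, pid = component_distance(np.array([[3, 3]]), tr, 0.1)
        assert np.isinf(d) and pid == -1

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n_pix = rng.integers(1, 12)
            pixels = rng.integers(0, 64, (n_pix, 2))
            polylines = [np.cumsum(rng.uniform(-1, 1.4, (rng.integers(2, 6), 2)),
                                   axis=0) + 3.0
                         for _ in range(rng.integers(1, 4))]
            polylines = [np.clip(p, 0.0, 6.4) for p in polylines]
            tr = ProcessTraces(polylines, 0.1, (64, 64))
            d, _ = component_distance(pixels, tr, 0.1)
            assert d == pytest.approx(
                brute_force_min_distance(pixels, polylines, 0.1), abs=1e-9)


# ---------------------------------------------------------------------------
# full detection with filters
# ---------------------------------------------------------------------------

def _disk_image(shape, spots, pixel_size=0.1, psf_sigma=0.2):
    """Noiseless image of blurred disks: spots = (x, y, r, amp)."""
    from punctapipe.synthetic import _add_disk

    arr = np.zeros(shape)
    for x, y, r, amp in spots:
        _add_disk(arr, x, y, r, amp, pixel_size)
    return ChannelImage(gaussian_filter(arr, psf_sigma / pixel_size,
                                        mode="constant"), pixel_size)


class TestDetectPuncta:
    def _fixture(self):
        """10 on-process spots, 2 distractors, 5 sub-area speckles."""
        tr = straight_trace(20.0, y_um=12.8, x0_um=2.0, image_shape=(256, 256))
        on = [(3.0 + 2.0 * k, 12.8, 0.45 + 0.05 * (k % 3), 200.0)
              for k in range(10)]                     # areas 0.64-0.95 µm²
        distractors = [(5.0, 4.0, 0.5, 200.0), (18.0, 21.0, 0.5, 200.0)]
        speckles = [(2.0 + 4.0 * k, 18.0, 0.10, 600.0) for k in range(5)]
        marker = _disk_image((256, 256), on + distractors + speckles)
        return tr, marker, on

    def test_exact_recovery_of_fixture(self):
        tr, marker, on = self._fixture()
        params = DetectionParams(threshold_mode="fixed", fixed_threshold=40.0)
        table, log = detect_puncta(marker, marker, tr, params)
        assert len(table) == 10
        assert log.n_removed_distance >= 2
        assert log.n_removed_area >= 5
        got = sorted(p.centroid_um[0] for p in table)
        np.testing.assert_allclose(got, sorted(x for x, *_ in on), atol=0.1)

    def test_area_filter_boundaries_inclusive(self):
        """Components of exactly 0.35 and 10 µm² are kept; just outside
        the window they are removed."""
        arr = np.zeros((200, 200))
        tr = ProcessTraces([np.array([[0.5, 10.0], [19.5, 10.0]])], 0.1,
                           (200, 200))
        # rectangles on the process line (row 99..), exact pixel counts
        arr[95:100, 10:17] = 255.0    # 35 px = 0.35 µm² -> kept
        arr[95:100, 30:36] = 255.0    # 30 px            -> removed (area)
        arr[80:120, 50:75] = 255.0    # 1000 px = 10 µm² -> kept
        arr[80:120, 90:116] = 255.0   # 1040 px          -> removed (area)
        marker = ChannelImage(arr, 0.1)
        params = DetectionParams(threshold_mode="fixed", fixed_threshold=100.0)
        table, log = detect_puncta(marker, marker, tr, params)
        kept_areas = sorted(p.area_um2 for p in table)
        assert kept_areas == pytest.approx([0.35, 10.0])
        assert log.n_removed_area == 2
        assert log.n_removed_distance == 0

    def test_distance_filter_boundary_inclusive(self):
        """Distance exactly 1.0 µm is kept; beyond it, removed.

        Uses a binary-exact calibration (0.125 µm/px) so the boundary
        comparison is exact in floating point."""
        arr = np.zeros((200, 200))
        y0 = (79 + 0.5) * 0.125  # line through pixel-centre row 79
        tr = ProcessTraces([np.array([[0.5, y0], [24.5, y0]])], 0.125,
                           (200, 200))
        arr[83:88, 20:30] = 255.0   # nearest row 83: 0.5 µm    -> kept
        arr[87:92, 50:60] = 255.0   # nearest row 87: 1.0 µm    -> kept
        arr[88:93, 80:90] = 255.0   # nearest row 88: 1.125 µm  -> removed
        marker = ChannelImage(arr, 0.125)
        params = DetectionParams(threshold_mode="fixed", fixed_threshold=100.0)
        table, log = detect_puncta(marker, marker, tr, params)
        kept_d = sorted(round(p.distance_um, 6) for p in table)
        assert kept_d == pytest.approx([0.5, 1.0])
        assert log.n_removed_distance == 1
        assert log.n_removed_area == 0

    def test_area_is_conserved_across_filters(self, rendered_image):
        _, traces, marker, signal, _ = rendered_image
        params = DetectionParams(threshold_mode="fixed", fixed_threshold=25.0)
        _, log = detect_puncta(marker, signal, traces, params)
        assert (log.kept_area_um2 + log.removed_area_um2
                == pytest.approx(log.total_foreground_area_um2))

    def test_filters_are_order_independent(self, rendered_image):
        """area∘distance == distance∘area == combined."""
        _, traces, marker, signal, _ = rendered_image
        fixed = dict(threshold_mode="fixed", fixed_threshold=25.0)
        combined, _ = detect_puncta(marker, signal, traces,
                                    DetectionParams(**fixed))
        area_only, _ = detect_puncta(marker, signal, traces,
                                     DetectionParams(**fixed,
                                                     max_distance=1e9))
        dist_only, _ = detect_puncta(
            marker, signal, traces,
            DetectionParams(**fixed, min_area=1e-6, max_area=1e9))
        key = lambda t: {p.centroid_um for p in t}
        assert key(combined) == key(area_only) & key(dist_only)

    def test_widening_filters_is_monotone(self, rendered_image):
        _, traces, marker, signal, _ = rendered_image
        fixed = dict(threshold_mode="fixed", fixed_threshold=25.0)
        n_narrow = len(detect_puncta(
            marker, signal, traces,
            DetectionParams(**fixed, min_area=0.5, max_area=2.0,
                            max_distance=0.5))[0])
        n_default = len(detect_puncta(marker, signal, traces,
                                      DetectionParams(**fixed))[0])
        n_wide = len(detect_puncta(
            marker, signal, traces,
            DetectionParams(**fixed, min_area=0.05, max_area=100.0,
                            max_distance=5.0))[0])
        assert n_narrow <= n_default <= n_wide

    def test_shape_mismatch_rejected(self):
        a = ChannelImage(np.zeros((8, 8)), 0.1)
        b = ChannelImage(np.zeros((8, 9)), 0.1)
        tr = ProcessTraces([], 0.1, (8, 8))
        with pytest.raises(ValueError, match="shapes differ"):
            detect_puncta(a, b, tr)

    def test_mean_intensities_from_raw_channels(self):
        """Signal means come from the raw signal channel, not the
        normalized marker."""
        tr = straight_trace(10.0, y_um=6.4, x0_um=1.0, image_shape=(128, 128))
        marker = _disk_image((128, 128), [(5.0, 6.4, 0.45, 200.0)])
        signal = ChannelImage(0.25 * marker.pixels, 0.1)
        params = DetectionParams(threshold_mode="fixed", fixed_threshold=40.0)
        table, _ = detect_puncta(marker, signal, tr, params)
        assert len(table) == 1
        p = table.puncta[0]
        assert p.mean_signal == pytest.approx(0.25 * p.mean_marker, rel=1e-9)
        assert p.signal_over_marker == pytest.approx(0.25, rel=1e-9)


class TestDetectionFidelity:
    def test_noiseless_recall_and_precision_are_perfect(self):
        from punctapipe import make_process_traces, render_image_pair
        from conftest import FIDELITY_PARAMS, fidelity_config

        for seed in range(5):
            cfg = fidelity_config(seed, background_sigma=0.0)
            tr = make_process_traces(cfg)
            marker, signal, truth = render_image_pair(tr, cfg)
            table, _ = detect_puncta(marker, signal, tr, FIDELITY_PARAMS)
            res = match_to_ground_truth(table, truth)
            assert res["recall"] == 1.0
            assert res["precision"] == 1.0
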