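import numpy as np
import pytest

from tilquant.imaging import (
    DetectionParams,
    detect_nuclei,
    histogram_of,
    max_entropy_threshold,
    mean_threshold,
    measure_cells,
)
from tilquant.model import SCALE_8BIT


def kapur_brute_force(hist: np.ndarray) -> int:
    """Independent exhaustive-search oracle for the maximum-entropy
    threshold: naive per-candidate recomputation of both class entropies."""
    p = np.asarray(hist, dtype=float)
    p = p / p.sum()
    best_t, best = None, -np.inf
    for t in range(len(p) - 1):
        w0 = p[: t + 1].sum()
        w1 = p[t + 1:].sum()
        if w0 <= 0 or w1 <= 0:
            continue
        h0 = -sum(q / w0 * np.log(q / w0) for q in p[: t + 1] if q > 0)
        h1 = -sum(q / w1 * np.log(q / w1) for q in p[t + 1:] if q > 0)
        if h0 + h1 > best + 1e-12:
            best, best_t = h0 + h1, t
    return best_t


class TestMeanThreshold:
    def test_two_delta_histogram(self):
        h = np.zeros(256)
        h[0], h[100] = 10, 10
        assert mean_threshold(h).threshold == 50

    def test_constant_image(self):
        h = np.zeros(256)
        h[42] = 1000
        assert mean_threshold(h).threshold == 42

    def test_equals_pixel_mean_on_random_images(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pixels = rng.integers(0, 256, size=1000)
            h = np.bincount(pixels, minlength=256)
            assert mean_threshold(h).threshold == round(float(pixels.mean()))

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            mean_threshold(np.zeros(256))


class TestMaxEntropyThreshold:
    def test_two_delta_separates(self):
        h = np.zeros(256)
        h[10], h[200] = 50, 50
        t = max_entropy_threshold(h).threshold
        assert 10 <= t < 200

    def test_matches_exhaustive_oracle_on_random_histograms(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n_levels = int(rng.integers(2, 65))
            h = np.zeros(n_levels)
            support = rng.choice(n_levels, size=rng.integers(2, n_levels + 1), replace=False)
            h[support] = rng.integers(1, 100, size=len(support))
            assert max_entropy_threshold(h).threshold == kapur_brute_force(h)

    def test_count_scale_invariance(self):
        rng = np.random.default_rng(2)
        h = rng.integers(0, 50, size=128).astype(float)
        h[[5, 90]] += 100
        t1 = max_entropy_threshold(h).threshold
        t2 = max_entropy_threshold(h * 7).threshold
        assert t1 == t2

    def test_single_level_rejected(self):
        h = np.zeros(256)
        h[7] = 10
        with pytest.raises(ValueError):
            max_entropy_threshold(h)


def _paint_nuclei(shape, centers, radius_px, value=None, noise_seed=99):
    # disks of per-nucleus brightness over a dim noise floor, as in a
    # fluorescence background with naturally varied chromatin signal
    rng = np.random.default_rng(noise_seed)
    img = rng.uniform(0, 5, size=shape)
    yy, xx = np.mgrid[0: shape[0], 0: shape[1]]
    for cx, cy in centers:
        v = value if value is not None else rng.uniform(120, 200)
        img[(xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px**2] = v
    return img


class TestDetectNuclei:
    params = DetectionParams(pixel_size_um=1.0)

    def test_blank_image_zero_nuclei(self):
        from tilquant.imaging import ThresholdResult

        labels, nuclei = detect_nuclei(
            np.zeros((64, 64)), self.params, ThresholdResult("dapi", "mean", 50)
        )
        assert labels.max() == 0 and len(nuclei) == 0

    def test_recall_and_centroid_accuracy_on_grid(self):
        # 50 non-overlapping nuclei on a jittered grid
        rng = np.random.default_rng(3)
        centers = []
        for i in range(10):
            for j in range(5):
                centers.append((20 + 25 * i + rng.uniform(-2, 2),
                                20 + 25 * j + rng.uniform(-2, 2)))
        img = _paint_nuclei((160, 280), centers, radius_px=3.2)
        thr = max_entropy_threshold(histogram_of(img.astype(np.uint8), SCALE_8BIT))
        labels, nuclei = detect_nuclei(img, self.params, thr)
        assert len(nuclei) >= 48
        # each detection within 2 um of a true center
        found = nuclei[["x_um", "y_um"]].to_numpy()
        true = np.asarray(centers)
        d = np.sqrt(((found[:, None, :] - true[None, :, :]) ** 2).sum(-1)).min(axis=1)
        assert (d < 2.0).all()

    def test_fused_pair_split_by_watershed(self):
        # two nuclei overlapping at ~60% of their diameters
        img = _paint_nuclei((64, 64), [(28, 32), (36, 32)], radius_px=5)
        from tilquant.imaging import ThresholdResult

        params = DetectionParams(pixel_size_um=1.0, seed_min_distance_um=3.0,
                                 nuclear_blur_sigma_um=0.5)
        labels, nuclei = detect_nuclei(img, params, ThresholdResult("dapi", "mean", 75))
        assert len(nuclei) == 2

    def test_watershed_conserves_foreground_pixels(self):
        # brightness 140: the half-peak contour (~70) lies below the global
        # threshold (75), so the refinement step is inert and watershed
        # must assign every foreground pixel to exactly one nucleus
        img = _paint_nuclei((96, 96), [(30, 30), (60, 60), (30, 66)], radius_px=4,
                            value=140)
        from tilquant.imaging import ThresholdResult
        from scipy import ndimage

        thr = ThresholdResult("dapi", "mean", 75)
        smoothed = ndimage.gaussian_filter(img, sigma=1.0)
        fg_area = int((smoothed > 75).sum())
        labels, _ = detect_nuclei(img, self.params, thr)
        assert (labels > 0).sum() == fg_area

    def test_halo_does_not_inflate_nucleus_area(self):
        # with a threshold far below the nucleus brightness, the blur halo
        # above the threshold must not count toward the nucleus area: the
        # half-peak contour keeps the measured area close to the painted disk
        img = _paint_nuclei((64, 64), [(32, 32)], radius_px=4, value=180)
        from tilquant.imaging import ThresholdResult

        labels, nuclei = detect_nuclei(img, self.params, ThresholdResult("dapi", "mean", 10))
        assert len(nuclei) == 1
        painted = np.pi * 4**2
        assert nuclei["nucleus_area_um2"].iloc[0] == pytest.approx(painted, rel=0.35)

    def test_count_invariant_to_intensity_rescaling(self):
        rng = np.random.default_rng(5)
        centers = [(20 + 28 * i, 20 + 28 * j) for i in range(3) for j in range(3)]
        img = np.random.default_rng(99).uniform(0, 4, size=(96, 96))
        yy, xx = np.mgrid[0:96, 0:96]
        for cx, cy in centers:
            v = rng.uniform(60, 100)
            img[(xx - cx) ** 2 + (yy - cy) ** 2 <= 16] = v
        h1 = histogram_of(img.astype(np.uint8), SCALE_8BIT)
        _, n1 = detect_nuclei(img, self.params, max_entropy_threshold(h1))
        img2 = img * 2.0
        h2 = histogram_of(img2.astype(np.uint8), SCALE_8BIT)
        _, n2 = detect_nuclei(img2, self.params, max_entropy_threshold(h2))
        assert len(n1) == len(n2) == 9


class TestMeasureCells:
    def test_constant_annulus_mean_equals_max(self):
        img = _paint_nuclei((48, 48), [(24, 24)], radius_px=4)
        from tilquant.imaging import ThresholdResult

        params = DetectionParams(pixel_size_um=1.0)
        labels, nuclei = detect_nuclei(img, params, ThresholdResult("dapi", "mean", 75))
        channels = np.zeros((4, 48, 48))
        channels[0] = img
        channels[2] = 120.0  # CD8 constant everywhere
        cells = measure_cells(labels, channels, params, nuclei)
        assert len(cells) == 1
        assert cells["cyto_mean_cd8"].iloc[0] == pytest.approx(120.0)
        assert cells["cyto_max_cd8"].iloc[0] == pytest.approx(120.0)

    def test_max_at_least_mean_under_noise(self):
        rng = np.random.default_rng(4)
        img = _paint_nuclei((96, 96), [(30, 30), (60, 60), (66, 30)], radius_px=4)
        from tilquant.imaging import ThresholdResult

        params = DetectionParams(pixel_size_um=1.0)
        labels, nuclei = detect_nuclei(img, params, ThresholdResult("dapi", "mean", 75))
        channels = rng.uniform(0, 200, size=(4, 96, 96))
        channels[0] = img
        cells = measure_cells(labels, channels, params, nuclei)
        assert len(cells) == 3
        for ch in ("cd3", "cd8", "panck"):
            assert (cells[f"cyto_max_{ch}"] >= cells[f"cyto_mean_{ch}"]).all()
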