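import numpy as np
import pytest
from scipy import ndimage

import conedetect as cd
from conedetect.probmap import (ProbabilityMap, extract_pixel_patches,
                                label_clusters)


# --------------------------------------------------------------------------
# Independent oracles
# --------------------------------------------------------------------------

def oracle_reconstruction(marker: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Morphological reconstruction by iterated 8-connected geodesic dilation."""
    rec = marker.astype(np.float64).copy()
    footprint = np.ones((3, 3))
    while True:
        dil = ndimage.grey_dilation(rec, footprint=footprint, mode="constant",
                                    cval=-np.inf)
        new = np.minimum(dil, mask)
        if np.array_equal(new, rec):
            return rec
        rec = new


def oracle_regional_maxima(v: np.ndarray) -> np.ndarray:
    """Plateau BFS: a regional max is an 8-connected equal-value region with
    every outside neighbor strictly lower."""
    h, w = v.shape
    out = np.zeros((h, w), dtype=bool)
    seen = np.zeros((h, w), dtype=bool)
    for sy in range(h):
        for sx in range(w):
            if seen[sy, sx]:
                continue
            val = v[sy, sx]
            stack, plateau, is_max = [(sy, sx)], [], True
            seen[sy, sx] = True
            while stack:
                y, x = stack.pop()
                plateau.append((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if not (0 <= ny < h and 0 <= nx < w):
                            continue
                        if v[ny, nx] > val:
                            is_max = False
                        elif v[ny, nx] == val and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
            if is_max:
                for y, x in plateau:
                    out[y, x] = True
    return out


def oracle_extended_maxima(v: np.ndarray, hgt: float) -> np.ndarray:
    return oracle_regional_maxima(oracle_reconstruction(v - hgt, v))


def oracle_mirror_padded(px: np.ndarray, half: int = 16) -> np.ndarray:
    """Explicit half-sample symmetric padding built from flipped slices."""
    top = px[:half][::-1]
    bot = px[-half:][::-1]
    v = np.concatenate([top, px, bot], axis=0)
    left = v[:, :half][:, ::-1]
    right = v[:, -half:][:, ::-1]
    return np.concatenate([left, v, right], axis=1)


# --------------------------------------------------------------------------
# Probability-map construction
# --------------------------------------------------------------------------

class TestPixelPatches:
    def test_corner_patch_matches_mirror_oracle(self, rng):
        px = rng.uniform(0, 255, (40, 45))
        img = cd.ConeImage(px)
        patches = extract_pixel_patches(img).reshape(40, 45, 33, 33)
        padded = oracle_mirror_padded(px)
        for (y, x) in [(0, 0), (0, 44), (39, 0), (39, 44), (20, 22)]:
            np.testing.assert_allclose(patches[y, x],
                                       padded[y:y + 33, x:x + 33], rtol=1e-6)

    def test_constant_image_gives_constant_map(self, trained_small_net):
        img = cd.ConeImage(np.zeros((40, 40)))
        pm = cd.compute_probability_map(trained_small_net, img)
        assert pm.shape == (40, 40)
        assert np.ptp(pm.values) < 1e-6
        assert 0 <= pm.values.min() and pm.values.max() <= 1


class TestSmoothing:
    def test_sigma_zero_identity(self, rng):
        pm = ProbabilityMap(rng.uniform(0, 1, (30, 30)))
        out = cd.smooth_map(pm, 0.0)
        np.testing.assert_array_equal(out.values, pm.values)

    def test_delta_spike_peak_matches_gaussian_normalization(self):
        v = np.zeros((41, 41))
        v[20, 20] = 1.0
        out = cd.smooth_map(ProbabilityMap(v), 1.3)
        expected = 1.0 / (2 * np.pi * 1.3 ** 2)
        assert out.values[20, 20] == pytest.approx(expected, rel=0.02)

    def test_never_increases_maximum_and_conserves_mass(self, rng):
        pm = ProbabilityMap(rng.uniform(0, 1, (50, 50)))
        out = cd.smooth_map(pm, 1.5)
        assert out.values.max() <= pm.values.max() + 1e-12
        assert abs(out.values.mean() - pm.values.mean()) < 1e-3

    def test_negative_sigma_rejected(self, rng):
        with pytest.raises(ValueError):
            cd.smooth_map(ProbabilityMap(rng.uniform(0, 1, (10, 10))), -1.0)


class TestExtendedMaxima:
    def test_constant_map_single_region(self):
        mask = cd.extended_maxima(np.full((12, 15), 0.4), 0.0)
        assert mask.all()

    def test_two_peak_toy_map(self):
        v = np.full((11, 11), 0.1)
        v[2, 2], v[8, 8] = 0.9, 0.6
        low = cd.extended_maxima(v, 0.2)
        assert low[2, 2] and low[8, 8]
        np.testing.assert_array_equal(low, oracle_extended_maxima(v, 0.2))
        high = cd.extended_maxima(v, 0.55)
        assert high[2, 2] and not high[8, 8]
        np.testing.assert_array_equal(high, oracle_extended_maxima(v, 0.55))

    @pytest.mark.parametrize("hgt", [0.0, 0.1, 0.3])
    def test_matches_bruteforce_oracle_on_random_maps(self, hgt):
        rng = np.random.default_rng(99)
        for _ in range(10):
            v = np.round(rng.uniform(0, 1, (20, 20)), 2)  # ties create plateaus
            np.testing.assert_array_equal(cd.extended_maxima(v, hgt),
                                          oracle_extended_maxima(v, hgt))

    def test_h_zero_is_regional_maxima(self, rng):
        v = rng.uniform(0, 1, (15, 15))
        np.testing.assert_array_equal(cd.extended_maxima(v, 0.0),
                                      cd.regional_maxima(v))


class TestLocalize:
    def _square_cluster_map(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[10:13, 10:13] = True
        sm = np.zeros((30, 30))
        sm[10:13, 10:13] = 0.8
        return mask, sm

    def test_centroid_of_symmetric_cluster(self):
        mask, sm = self._square_cluster_map()
        cones = cd.localize_cones(mask, sm, 0.5)
        assert len(cones) == 1
        np.testing.assert_allclose(cones.points[0], [11.0, 11.0])

    def test_threshold_removes_weak_cluster(self):
        mask, sm = self._square_cluster_map()
        assert len(cd.localize_cones(mask, sm, 0.9)) == 0

    def test_l_shaped_cluster_centroid(self):
        mask = np.zeros((10, 10), dtype=bool)
        for y, x in [(0, 0), (0, 1), (1, 0)]:
            mask[y, x] = True
        cones = cd.localize_cones(mask, np.ones((10, 10)), 0.5)
        np.testing.assert_allclose(cones.points[0], [1 / 3, 1 / 3])

    def test_weighted_centroid_pulls_toward_high_probability(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[5, 4:7] = True  # horizontal 3-pixel cluster
        sm = np.zeros((10, 10))
        sm[5, 4:7] = [0.2, 0.3, 0.9]
        plain = cd.localize_cones(mask, sm, 0.1)
        weighted = cd.localize_cones(mask, sm, 0.1, weighted=True)
        assert plain.points[0][0] == pytest.approx(5.0)
        assert weighted.points[0][0] > 5.3  # shifted toward the bright pixel

    def test_raising_threshold_never_adds_cones(self, rng):
        v = cd.smooth_map(ProbabilityMap(rng.uniform(0, 1, (60, 60))), 1.0)
        mask = cd.extended_maxima(v, 0.05)
        counts = [len(cd.localize_cones(mask, v, t)) for t in np.linspace(0.1, 0.9, 9)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_centroids_inside_cluster_bbox(self, rng):
        v = cd.smooth_map(ProbabilityMap(rng.uniform(0, 1, (50, 50))), 0.8)
        mask = cd.extended_maxima(v, 0.02)
        cs = label_clusters(mask, v)
        for i in range(cs.n):
            ys, xs = np.nonzero(cs.labels == i + 1)
            cx, cy = cs.centroids[i]
            assert xs.min() <= cx <= xs.max() and ys.min() <= cy <= ys.max()


class TestDetect:
    def test_constant_offset_invariance(self, trained_small_net):
        img, _ = cd.generate_mosaic(cd.MosaicParams(image_size=48, rng_seed=11))
        params = cd.DetectionParams(1.0, 0.0, 0.3)
        a = cd.detect_cones(img, trained_small_net, params)
        shifted = cd.ConeImage(img.pixels + 50.0, scale=img.scale)
        b = cd.detect_cones(shifted, trained_small_net, params)
        np.testing.assert_allclose(a.points, b.points, atol=1e-9)
        # detections lie within image bounds
        assert np.all(a.points >= 0)
        assert np.all(a.points[:, 0] <= 47) and np.all(a.points[:, 1] <= 47)

    def test_published_parameter_defaults(self):
        assert cd.CONFOCAL_PARAMS.astuple() == (1.3, 0.0, 0.3)
        assert cd.SPLITDETECTOR_PARAMS.astuple() == (2.0, 0.1, 0.5)
        assert cd.MIXED_PARAMS.astuple() == (0.4, 0.25, 0.9)
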