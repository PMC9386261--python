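"""Channel-weighted region contrast: distances, segmentation, saliency."""

import math

import numpy as np
import pytest

from chromasal import colorspace as cs
from chromasal import rncw as R
from chromasal import synthetic as S
from chromasal.fixations import SalientColorTable


class TestChannelWeights:
    def test_defaults_are_the_mic_derived_weights(self):
        w = R.ChannelWeights()
        assert (w.w_L, w.w_a, w.w_b) == pytest.approx((0.32, 0.28, 0.40))

    def test_from_mic_profile_normalizes(self):
        w = R.ChannelWeights.from_mic_profile({"L": 0.61, "a": 0.52, "b": 0.76})
        assert w.w_L + w.w_a + w.w_b == pytest.approx(1.0)
        assert round(w.w_L, 2) == 0.32
        assert round(w.w_a, 2) == 0.28
        assert round(w.w_b, 2) == 0.40

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            R.ChannelWeights(-0.1, 0.5, 0.6)


class TestPixelDistance:
    def test_identical_pixels_zero(self):
        assert R.pixel_distance([50, 10, -20], [50, 10, -20]) == 0.0

    def test_pure_lightness_contrast(self):
        d = R.pixel_distance([100, 0, 0], [0, 0, 0])
        assert d == pytest.approx(100 * math.sqrt(0.32))

    def test_equal_weights_is_scaled_euclidean(self, rng):
        w = R.ChannelWeights.equal()
        for _ in range(20):
            p = rng.uniform(-50, 50, 3)
            q = rng.uniform(-50, 50, 3)
            assert R.pixel_distance(p, q, w) == pytest.approx(
                np.linalg.norm(p - q) / math.sqrt(3))


class TestSegmentation:
    def test_uniform_image_single_region(self):
        lab = np.zeros((10, 12, 3))
        lab[..., 0] = 50
        labels = R.segment(lab, smooth_sigma=0)
        assert labels.max() == 0

    def test_two_distinct_halves(self):
        lab = np.zeros((10, 12, 3))
        lab[..., 0] = 20
        lab[:, 6:, 0] = 90
        labels = R.segment(lab, k=10, min_size=5, smooth_sigma=0)
        assert labels.max() == 1
        assert (labels[:, :6] == labels[0, 0]).all()
        assert (labels[:, 6:] == labels[0, 6]).all()
        assert labels[0, 0] != labels[0, 6]

    def test_partition_and_min_size(self, rng):
        lab = np.zeros((20, 20, 3))
        lab[..., 0] = rng.uniform(0, 100, (20, 20))
        labels = R.segment(lab, k=50, min_size=8, smooth_sigma=0)
        n = labels.max() + 1
        counts = np.bincount(labels.ravel(), minlength=n)
        assert counts.sum() == 400
        assert (counts >= 8).all()
        assert set(np.unique(labels)) == set(range(n))

    def test_bad_params_rejected(self):
        lab = np.zeros((4, 4, 3))
        with pytest.raises(ValueError):
            R.segment(lab, k=0)
        with pytest.raises(ValueError):
            R.segment(lab, min_size=0)
        with pytest.raises(ValueError):
            R.segment(lab, connectivity=6)


def _region(codes_freqs, count, centroid):
    codes = np.array([c for c, _ in codes_freqs], dtype=np.int64)
    freqs = np.array([f for _, f in codes_freqs])
    return R.Region(id=0, pixel_count=count, centroid=centroid,
                    codes=codes, freqs=freqs)


def _brute_region_distance(rx, ry, w):
    total = 0.0
    for cx, fx in zip(rx.codes, rx.freqs):
        for cy, fy in zip(ry.codes, ry.freqs):
            px = cs.code_to_lab_center(int(cx))
            py = cs.code_to_lab_center(int(cy))
            d = math.sqrt(w.w_L * (px[0] - py[0]) ** 2
                          + w.w_a * (px[1] - py[1]) ** 2
                          + w.w_b * (px[2] - py[2]) ** 2)
            total += fx * fy * d
    return total


class TestRegionContrast:
    def test_identical_single_color_regions_zero(self):
        ra = _region([(100, 1.0)], 10, (0.2, 0.2))
        rb = _region([(100, 1.0)], 20, (0.8, 0.8))
        assert R.region_color_distance(ra, rb) == 0.0

    def test_two_single_colors_equal_pixel_distance(self):
        ra = _region([(0, 1.0)], 5, (0.1, 0.1))
        rb = _region([(4095, 1.0)], 5, (0.9, 0.9))
        d = R.region_color_distance(ra, rb)
        expect = R.pixel_distance(cs.code_to_lab_center(0),
                                  cs.code_to_lab_center(4095))
        assert d == pytest.approx(float(expect))

    def test_multicolor_regions_match_scalar_loop(self, rng):
        w = R.ChannelWeights()
        ra = _region([(10, 0.5), (200, 0.3), (3000, 0.2)], 30, (0.3, 0.4))
        rb = _region([(99, 0.6), (2048, 0.4)], 50, (0.7, 0.6))
        assert R.region_color_distance(ra, rb, w) == pytest.approx(
            _brute_region_distance(ra, rb, w))

    @pytest.fixture
    def three_regions(self):
        return [
            _region([(10, 0.7), (20, 0.3)], 40, (0.2, 0.2)),
            _region([(2000, 1.0)], 25, (0.5, 0.8)),
            _region([(4000, 0.5), (300, 0.5)], 35, (0.9, 0.3)),
        ]

    def test_plain_saliency_matches_brute_force(self, three_regions):
        w = R.ChannelWeights()
        got = R.region_saliency_plain(three_regions, w)
        for i, rx in enumerate(three_regions):
            expect = rx.pixel_count * sum(
                _brute_region_distance(rx, ry, w)
                for j, ry in enumerate(three_regions) if j != i)
            assert got[i] == pytest.approx(expect)

    def test_plain_saliency_legacy_weighting(self, three_regions):
        w = R.ChannelWeights()
        got = R.region_saliency_plain(three_regions, w, legacy_rc_weighting=True)
        for i, rx in enumerate(three_regions):
            expect = sum(
                ry.pixel_count * _brute_region_distance(rx, ry, w)
                for j, ry in enumerate(three_regions) if j != i)
            assert got[i] == pytest.approx(expect)

    def test_spatial_saliency_matches_brute_force(self, three_regions):
        w = R.ChannelWeights()
        sigma_s2 = 0.4
        got = R.region_saliency_spatial(three_regions, w, sigma_s2)
        for i, rx in enumerate(three_regions):
            acc = 0.0
            for j, ry in enumerate(three_regions):
                if j == i:
                    continue
                ds = math.dist(rx.centroid, ry.centroid)
                acc += (math.exp(-ds / sigma_s2) * ry.pixel_count
                        * _brute_region_distance(rx, ry, w))
            assert got[i] == pytest.approx(rx.pixel_count * acc)

    def test_spatial_reduces_to_plain_in_large_sigma_limit(self, three_regions):
        w = R.ChannelWeights()
        spatial = R.region_saliency_spatial(three_regions, w, sigma_s2=1e9)
        plain_weighted = R.region_saliency_plain(three_regions, w,
                                                 legacy_rc_weighting=True)
        counts = np.array([r.pixel_count for r in three_regions], dtype=float)
        assert np.allclose(spatial, counts * plain_weighted)

    def test_single_region_zero(self):
        r0 = [_region([(5, 1.0)], 9, (0.5, 0.5))]
        assert R.region_saliency_plain(r0)[0] == 0.0
        assert R.region_saliency_spatial(r0)[0] == 0.0

    def test_identical_color_regions_zero(self):
        regs = [_region([(7, 1.0)], 10, (0.2, 0.5)),
                _region([(7, 1.0)], 30, (0.8, 0.5))]
        assert np.allclose(R.region_saliency_plain(regs), 0.0)


class TestReducePalette:
    def test_identity_cases(self, rng):
        codes = rng.integers(0, 4096, size=(6, 6)).astype(np.int32)
        assert np.array_equal(R.reduce_palette(codes, coverage=1.0), codes)
        two = np.where(np.arange(36).reshape(6, 6) % 2 == 0, 5, 900).astype(np.int32)
        assert np.array_equal(R.reduce_palette(two, coverage=0.5), two)

    def test_known_frequency_cut(self):
        # 10 codes with frequencies 20,15,...; 0.8 coverage keeps the top
        # codes whose cumulative share first reaches 80%
        freqs = [20, 15, 12, 10, 9, 8, 7, 7, 6, 6]
        codes = np.repeat(np.arange(0, 4000, 400), freqs)
        rng = np.random.default_rng(0)
        rng.shuffle(codes)
        codes = codes.reshape(10, 10)
        out = R.reduce_palette(codes, coverage=0.8)
        kept = set(np.unique(out).tolist())
        cum = np.cumsum(freqs) / 100
        n_keep = int(np.searchsorted(cum, 0.8)) + 1  # brute cumulative cut
        assert kept == set(int(c) for c in range(0, 400 * n_keep, 400))

    def test_dropped_codes_remap_to_nearest_kept(self):
        codes = np.full((5, 5), 0, dtype=np.int32)
        codes[:, 3:] = 4095
        codes[0, 0] = 1  # rare code, bin-center nearest to code 0
        out = R.reduce_palette(codes, coverage=0.9)
        assert out[0, 0] == 0
        assert set(np.unique(out).tolist()) == {0, 4095}

    def test_bad_coverage_rejected(self):
        with pytest.raises(ValueError):
            R.reduce_palette(np.zeros((2, 2), dtype=int), coverage=0.0)


class TestDetector:
    def test_uniform_image_all_zero(self):
        img = np.full((20, 24, 3), 130, dtype=np.uint8)
        assert np.allclose(R.rncw(img), 0.0)

    def test_popout_object_outranks_background(self, sod_fixture):
        img, mask = sod_fixture
        sal = R.rncw(img)
        assert sal[mask > 0].mean() > sal[mask == 0].mean() + 0.5

    def test_equal_weights_ranking_matches_plain_rc(self):
        """With equal channel weights the weighted distance is Euclidean/sqrt3,
        so region rankings must match an unweighted RC computation exactly."""
        for seed in range(20):
            img, _ = S.generate_sod_fixture(seed=seed, size=(48, 64))
            lab = cs.rgb_to_lab(img)
            labels = R.segment(lab, R.ChannelWeights.equal(), k=100, min_size=20)
            codes = cs.quantize_lab(lab)
            regions = R.build_regions(labels, codes)
            ours = R.region_saliency_spatial(regions, R.ChannelWeights.equal())
            # independent RC-style oracle: plain Euclidean Lab distances
            n = len(regions)
            rc = np.zeros(n)
            for i in range(n):
                acc = 0.0
                for j in range(n):
                    if i == j:
                        continue
                    li = cs.code_to_lab_center(regions[i].codes)
                    lj = cs.code_to_lab_center(regions[j].codes)
                    d = np.sqrt(((li[:, None] - lj[None, :]) ** 2).sum(-1))
                    dwr = regions[i].freqs @ d @ regions[j].freqs
                    ds = math.dist(regions[i].centroid, regions[j].centroid)
                    acc += math.exp(-ds / 0.4) * regions[j].pixel_count * dwr
                rc[i] = regions[i].pixel_count * acc
            assert np.array_equal(np.argsort(ours, kind="stable"),
                                  np.argsort(rc, kind="stable"))
            assert np.allclose(ours * math.sqrt(3), rc)

    def test_invariant_under_uniform_lightness_shift(self):
        """Shifting every pixel's L by one quantizer bin width leaves all
        pairwise distances (and hence the map) unchanged."""
        rng = np.random.default_rng(3)
        lab = np.zeros((24, 32, 3))
        lab[..., 0] = rng.uniform(20, 60, (24, 32))
        lab[..., 1] = rng.uniform(-30, 30, (24, 32))
        lab[..., 2] = rng.uniform(-30, 30, (24, 32))
        lab[..., 0] = (2.55 * lab[..., 0] // 16 * 16 + 8) / 2.55  # bin centers
        shift = 16 / 2.55

        def run(lab_img):
            labels = R.segment(lab_img, k=100, min_size=10, smooth_sigma=0)
            regions = R.build_regions(labels, cs.quantize_lab(lab_img))
            scores = R.region_saliency_spatial(regions)
            sal = scores[labels]
            lo, hi = sal.min(), sal.max()
            return (sal - lo) / (hi - lo) if hi > lo else sal * 0

        shifted = lab.copy()
        shifted[..., 0] += shift
        assert np.allclose(run(lab), run(shifted))

    def test_isoluminant_object_loses_contrast_in_grayscale(self):
        img, mask = S.generate_sod_fixture(seed=2, isoluminant=True)
        gray = cs.rgb_to_gray(img)
        _, _, _, scores_c = R.rncw(img, return_parts=True)
        _, _, _, scores_g = R.rncw(gray, return_parts=True)
        assert scores_g.max() < 0.1 * scores_c.max()


class TestColorPrior:
    def test_uniform_table_is_identity(self, sod_fixture):
        img, _ = sod_fixture
        sal = R.rncw(img)
        codes = cs.quantize_lab(cs.rgb_to_lab(img))
        table = SalientColorTable(
            entries={int(c): 0.7 for c in np.unique(codes)}, support={})
        out = R.apply_color_prior(sal, img, table)
        assert np.array_equal(out, sal)

    def test_empty_table_is_identity(self, sod_fixture):
        img, _ = sod_fixture
        sal = R.rncw(img)
        out = R.apply_color_prior(sal, img, SalientColorTable({}, {}))
        assert np.array_equal(out, sal)

    def test_hand_evaluated_reweighting(self):
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        img[:, :2] = [255, 0, 0]          # salient color on the left
        img[:, 2:] = [0, 0, 255]
        codes = cs.quantize_lab(cs.rgb_to_lab(img))
        left_code = int(codes[0, 0])
        sal = np.full((4, 4), 0.5)
        table = SalientColorTable(entries={left_code: 0.8}, support={})
        out = R.apply_color_prior(sal, img, table, floor=0.1)
        # left: 0.5*0.8 -> rescale by 0.5/0.4 -> 0.5 ; right: 0.5*0.1*1.25 = 0.0625
        assert np.allclose(out[:, :2], 0.5)
        assert np.allclose(out[:, 2:], 0.0625)

    def test_never_increases_maximum(self, sod_fixture, rng):
        img, _ = sod_fixture
        sal = R.rncw(img)
        codes = np.unique(cs.quantize_lab(cs.rgb_to_lab(img)))
        table = SalientColorTable(
            entries={int(c): float(w) for c, w in
                     zip(codes, rng.uniform(0.2, 1.0, codes.size))},
            support={})
        out = R.apply_color_prior(sal, img, table)
        assert out.max() <= sal.max() + 1e-12

    def test_all_zero_map_passthrough(self):
        img = np.full((3, 3, 3), 99, dtype=np.uint8)
        sal = np.zeros((3, 3))
        out = R.apply_color_prior(sal, img, SalientColorTable({}, {}))
        assert np.array_equal(out, sal)
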