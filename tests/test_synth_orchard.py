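"""Synthetic scene generation, augmentations, splitting and label I/O."""

import numpy as np
import pytest

from citrusdet.synth_orchard import (CLASSES, LabeledImage, MIN_VISIBLE_AREA,
                                     PackingError, SceneSpec, TreeCountPair,
                                     generate_scene, generate_tree_views,
                                     mixup, mosaic, photometric_augment,
                                     read_yolo_labels, split_dataset,
                                     write_yolo_labels)


class TestGenerateScene:
    def test_zero_counts_give_empty_labels(self):
        s = generate_scene(SceneSpec(counts=(0, 0, 0), seed=1))
        assert s.labels == []
        assert s.image.shape == (640, 640, 3)

    def test_deterministic_under_seed(self):
        a = generate_scene(SceneSpec(seed=9))
        b = generate_scene(SceneSpec(seed=9))
        assert np.array_equal(a.image, b.image)
        assert a.labels == b.labels

    def test_unoccluded_fruit_all_labeled_near_square(self):
        s = generate_scene(SceneSpec(counts=(0, 0, 12),
                                     occlusion_fraction=0.0, seed=5))
        assert len(s.labels) == 12
        for cls, cx, cy, w, h in s.labels:
            assert cls == 2
            assert 0 <= cx - w / 2 and cx + w / 2 <= 1
            assert 0 <= cy - h / 2 and cy + h / 2 <= 1
            assert 0.8 <= (w / h) <= 1.25

    def test_labels_in_unit_square_and_visible_area_floor(self):
        s = generate_scene(SceneSpec(counts=(3, 5, 5),
                                     occlusion_fraction=0.6, seed=11))
        assert len(s.labels) <= 13
        for _, cx, cy, w, h in s.labels:
            assert all(0.0 <= v <= 1.0 for v in (cx, cy, w, h))
            assert (w * 640) * (h * 640) >= MIN_VISIBLE_AREA

    def test_aspect_ratio_median_close_to_square(self):
        ars = []
        for seed in range(12):
            s = generate_scene(SceneSpec(seed=seed, occlusion_fraction=0.0,
                                         width=320, height=320,
                                         counts=(2, 3, 3)))
            ars += [w / h for _, _, _, w, h in s.labels]
        assert 0.95 <= float(np.median(ars)) <= 1.05

    def test_impossible_packing_raises(self):
        with pytest.raises(PackingError):
            generate_scene(SceneSpec(width=64, height=64,
                                     counts=(200, 200, 200)))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(width=32)
        with pytest.raises(ValueError):
            SceneSpec(counts=(-1, 0, 0))
        with pytest.raises(ValueError):
            SceneSpec(lighting_gamma=0.0)


class TestPhotometric:
    def test_gamma_one_is_identity(self, rng):
        img = rng.integers(0, 256, (8, 8, 3)).astype(np.uint8)
        np.testing.assert_array_equal(
            photometric_augment(img, "gamma", 1.0), img)

    def test_gamma_two_hand_value(self):
        img = np.full((4, 4, 3), 128, np.uint8)
        out = photometric_augment(img, "gamma", 2.0)
        assert np.all(out == 64)        # 255*(128/255)^2 = 64.25 -> 64

    def test_equalize_constant_image_unchanged(self):
        img = np.full((6, 6, 3), 77, np.uint8)
        np.testing.assert_array_equal(
            photometric_augment(img, "equalize"), img)

    def test_equalize_spreads_luminance(self, rng):
        img = rng.integers(100, 140, (32, 32, 3)).astype(np.uint8)
        out = photometric_augment(img, "equalize")
        assert np.ptp(out) > np.ptp(img)

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            photometric_augment(np.zeros((2, 2, 3), np.uint8), "gamma", 0.0)


class TestMixup:
    def test_lam_one_keeps_first_pixels_and_unions_labels(self):
        a = LabeledImage(np.full((4, 4, 3), 10, np.uint8),
                         [(0, 0.5, 0.5, 0.2, 0.2)])
        b = LabeledImage(np.full((4, 4, 3), 200, np.uint8),
                         [(1, 0.3, 0.3, 0.1, 0.1)])
        out = mixup(a, b, 1.0)
        np.testing.assert_array_equal(out.image, a.image)
        assert out.labels == a.labels + b.labels

    def test_half_blend_of_constants(self):
        a = LabeledImage(np.full((4, 4, 3), 100, np.uint8))
        b = LabeledImage(np.full((4, 4, 3), 200, np.uint8))
        assert np.all(mixup(a, b, 0.5).image == 150)

    def test_label_count_always_sums(self, rng):
        a = LabeledImage(np.zeros((4, 4, 3), np.uint8),
                         [(0, 0.5, 0.5, 0.1, 0.1)] * 3)
        b = LabeledImage(np.zeros((4, 4, 3), np.uint8),
                         [(1, 0.5, 0.5, 0.1, 0.1)] * 5)
        assert len(mixup(a, b, 0.3).labels) == 8

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mixup(LabeledImage(np.zeros((4, 4, 3), np.uint8)),
                  LabeledImage(np.zeros((6, 6, 3), np.uint8)), 0.5)


class TestMosaic:
    def _solid(self, v, n=1):
        return LabeledImage(np.full((32, 32, 3), v, np.uint8),
                            [(0, 0.5, 0.5, 0.5, 0.5)] * n)

    def test_four_solid_images_tile_their_quadrants(self):
        quad = [self._solid(v) for v in (40, 90, 140, 190)]
        out = mosaic(quad, canvas_size=64, seed=3)
        vals = set(np.unique(out.image))
        assert vals <= {40, 90, 140, 190}
        assert len(vals) == 4

    def test_labels_match_hand_affine_transform(self):
        quad = [self._solid(v) for v in (40, 90, 140, 190)]
        out = mosaic(quad, canvas_size=64, seed=3)
        # recover the junction from the solid tile boundaries
        jx = int(np.argmax(out.image[0, :, 0] != 40))
        jy = int(np.argmax(out.image[:, 0, 0] != 40))
        rects = [(0, 0, jx, jy), (jx, 0, 64 - jx, jy),
                 (0, jy, jx, 64 - jy), (jx, jy, 64 - jx, 64 - jy)]
        expect = []
        for (x0, y0, qw, qh) in rects:
            x1, x2 = x0 + 0.25 * qw, x0 + 0.75 * qw
            y1, y2 = y0 + 0.25 * qh, y0 + 0.75 * qh
            expect.append((0, (x1 + x2) / 128, (y1 + y2) / 128,
                           (x2 - x1) / 64, (y2 - y1) / 64))
        assert len(out.labels) == 4
        for got, exp in zip(sorted(out.labels), sorted(expect)):
            np.testing.assert_allclose(got, exp, atol=1e-9)

    def test_label_count_never_grows_and_stays_in_bounds(self, rng):
        quad = [self._solid(50, n=int(rng.integers(0, 4))) for _ in range(4)]
        out = mosaic(quad, canvas_size=48, seed=7)
        assert len(out.labels) <= sum(len(q.labels) for q in quad)
        for _, cx, cy, w, h in out.labels:
            assert 0 <= cx - w / 2 and cx + w / 2 <= 1
            assert 0 <= cy - h / 2 and cy + h / 2 <= 1

    def test_requires_four_inputs(self):
        with pytest.raises(ValueError):
            mosaic([self._solid(1)] * 3)


class TestSplit:
    def test_reference_dataset_sizes(self):
        tr, va, te = split_dataset(range(3250))
        assert (len(tr), len(va), len(te)) == (2275, 325, 650)

    def test_ten_items(self):
        sizes = [len(s) for s in split_dataset(range(10))]
        assert sizes == [7, 1, 2]

    def test_deterministic_and_partition(self):
        a = split_dataset(range(101), seed=5)
        b = split_dataset(range(101), seed=5)
        assert a == b
        flat = [x for part in a for x in part]
        assert sorted(flat) == list(range(101))
        assert len(set(flat)) == 101

    def test_sizes_within_one_of_exact_ratios(self):
        for n in (10, 33, 97, 1234):
            parts = split_dataset(range(n))
            for part, r in zip(parts, (0.7, 0.1, 0.2)):
                assert abs(len(part) - r * n) < 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([])


class TestLabelIO:
    def test_empty_list_writes_empty_file(self, tmp_path):
        p = tmp_path / "l.txt"
        write_yolo_labels([], p)
        assert p.read_text() == ""
        assert read_yolo_labels(p) == []

    def test_roundtrip_precision(self, tmp_path, rng):
        labels = [(int(rng.integers(0, 3)), *rng.uniform(0.05, 0.95, 4))
                  for _ in range(100)]
        p = tmp_path / "l.txt"
        write_yolo_labels(labels, p)
        back = read_yolo_labels(p)
        err = np.abs(np.array(labels) - np.array(back)).max()
        assert err < 1e-6

    def test_single_line_parse(self, tmp_path):
        p = tmp_path / "l.txt"
        p.write_text("0 0.5 0.5 0.1 0.1\n")
        assert read_yolo_labels(p) == [(0, 0.5, 0.5, 0.1, 0.1)]

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "l.txt"
        p.write_text("0 0.5 0.5 0.1 0.1\n1 0.2 broken\n")
        with pytest.raises(ValueError, match=":2"):
            read_yolo_labels(p)


class TestTreeViews:
    def test_full_visibility_no_noise_is_identity(self):
        pairs = generate_tree_views(20, visibility=1.0, sigma=0.0, seed=4)
        assert all(p.detect == p.actual for p in pairs)

    def test_deterministic_under_seed(self):
        assert generate_tree_views(15, seed=2) == generate_tree_views(15, seed=2)

    def test_counts_bounded_and_in_range(self):
        pairs = generate_tree_views(200, seed=8)
        assert all(0 <= p.detect <= p.actual for p in pairs)
        assert all(50 <= p.actual <= 140 for p in pairs)

    def test_invalid_visibility_rejected(self):
        with pytest.raises(ValueError):
            generate_tree_views(5, visibility=1.5)
        with pytest.raises(ValueError):
            TreeCountPair(1, 10, 5)

    def test_linear_fit_recovers_slope(self):
        from citrusdet.yield_model import fit_polynomial
        pairs = generate_tree_views(50, alpha=1.44, beta=1.0, sigma=5.0,
                                    seed=3)
        fit = fit_polynomial([(p.detect, p.actual) for p in pairs], 1)
        assert abs(fit.coefficients[1] - 1.44) / 1.44 < 0.10
        assert fit.r2_plain > 0.8
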