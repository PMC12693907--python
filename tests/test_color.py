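import json

import numpy as np
import pytest
from hypothesis import given, strategies as st
from skimage.color import rgb2lab

from tomaqual import color

from oracles import point_in_polygon


def uniform_image(r, g, b, size=8):
    img = np.zeros((size, size, 3), dtype=np.uint8)
    img[..., 0], img[..., 1], img[..., 2] = r, g, b
    return img


class TestGrayWorldBalance:
    def test_uniform_gray_is_fixed_point(self):
        img = uniform_image(128, 128, 128)
        balanced, gains = color.gray_world_balance(img)
        np.testing.assert_array_equal(balanced, img)
        assert gains.gains == pytest.approx((1.0, 1.0, 1.0))

    def test_gains_from_channel_means(self):
        img = uniform_image(100, 50, 150)
        _, gains = color.gray_world_balance(img)
        assert gains.a_gray == pytest.approx(100.0)
        assert gains.gains == pytest.approx((1.0, 2.0, 2.0 / 3.0))
        # the defining identity s_c · a_c = a_gray
        for s, a in zip(gains.gains, (gains.a_r, gains.a_g, gains.a_b)):
            assert s * a == pytest.approx(gains.a_gray)

    def test_balanced_channel_means_equal_pre_clipping(self, rng):
        img = rng.integers(20, 200, size=(32, 32, 3)).astype(np.uint8)
        _, gains = color.gray_world_balance(img)
        pre_clip_means = img.reshape(-1, 3).mean(axis=0) * np.array(gains.gains)
        assert np.ptp(pre_clip_means) < 1e-9

    def test_idempotent_within_clipping(self, rng):
        img = rng.integers(60, 180, size=(16, 16, 3)).astype(np.uint8)
        balanced, _ = color.gray_world_balance(img)
        _, gains2 = color.gray_world_balance(balanced)
        # means already equalized → second-pass gains are ≈ 1
        assert np.allclose(gains2.gains, 1.0, atol=0.01)

    def test_zero_channel_mean_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            color.gray_world_balance(uniform_image(100, 0, 100))


class TestAStarExtraction:
    def test_achromatic_pixels_give_zero(self):
        for v in (0, 1, 40, 128, 255):
            a = color.a_star_channel(uniform_image(v, v, v))
            assert np.abs(a).max() < 1e-6

    def test_pure_red_matches_reference_colorimetry(self):
        img = uniform_image(255, 0, 0)
        mask = np.ones(img.shape[:2], dtype=bool)
        a_mean, a_norm = color.rgb_to_a(img, mask)
        reference = rgb2lab(img.astype(float) / 255.0)[0, 0, 1]  # independent oracle
        assert a_mean == pytest.approx(reference, abs=0.05)
        assert a_mean == pytest.approx(80.1, abs=0.1)

    def test_a_norm_of_zero_a(self):
        img = uniform_image(90, 90, 90)
        _, a_norm = color.rgb_to_a(img, np.ones((8, 8), dtype=bool))
        assert a_norm == pytest.approx(128.0 / 255.0, abs=1e-6)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="no pixels"):
            color.rgb_to_a(uniform_image(1, 2, 3), np.zeros((8, 8), dtype=bool))

    @given(
        g=st.integers(0, 200),
        b=st.integers(0, 200),
        r1=st.integers(0, 254),
        dr=st.integers(1, 60),
    )
    def test_monotone_in_redness(self, g, b, r1, dr):
        r2 = min(r1 + dr, 255)
        a1 = color.a_star_channel(uniform_image(r1, g, b))[0, 0]
        a2 = color.a_star_channel(uniform_image(r2, g, b))[0, 0]
        assert a2 > a1


class TestColorRatios:
    def disc(self, fractions):
        from tomaqual.simulate import render_fruit_image

        return render_fruit_image(np.asarray(fractions, dtype=float), size=64, seed=0)

    @pytest.mark.parametrize(
        "fractions", [(1.0, 0.0, 0.0), (0.5, 0.0, 0.5), (1 / 3, 1 / 3, 1 / 3)]
    )
    def test_synthetic_disc_fractions_recovered(self, fractions):
        img, mask = self.disc(fractions)
        measured = color.color_ratios(img, mask)
        assert measured == pytest.approx(fractions, abs=0.02)
        assert sum(measured) == pytest.approx(1.0, abs=1e-9)

    def test_translation_invariance(self):
        img, mask = self.disc((0.4, 0.2, 0.4))
        big = np.full((96, 96, 3), 180, dtype=np.uint8)
        big_mask = np.zeros((96, 96), dtype=bool)
        big[20:84, 10:74] = img
        big_mask[20:84, 10:74] = mask
        assert color.color_ratios(big, big_mask) == pytest.approx(
            color.color_ratios(img, mask), abs=1e-12
        )

    def test_low_saturation_pixels_unclassified(self):
        with pytest.raises(ValueError, match="hue bands"):
            color.color_ratios(uniform_image(128, 128, 128), np.ones((8, 8), dtype=bool))


class TestGradeMaturity:
    @pytest.mark.parametrize(
        "red, yellow, level",
        [
            (0.0, 0.0, 1),
            (0.05, 0.03, 2),
            (0.25, 0.0, 3),
            (0.50, 0.0, 4),
            (0.90, 0.0, 5),
        ],
    )
    def test_grading_table(self, red, yellow, level):
        assert color.grade_maturity(red, yellow) == level

    def test_monotone_in_red_fraction(self):
        grid = np.linspace(0, 1, 101)
        levels = [color.grade_maturity(r) for r in grid]
        assert all(b >= a for a, b in zip(levels, levels[1:]))

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            color.grade_maturity(1.2)


class TestPolygonMask:
    def write_annotation(self, tmp_path, shapes, h=20, w=20):
        path = tmp_path / "fruit.json"
        path.write_text(
            json.dumps(
                {"imageHeight": h, "imageWidth": w,
                 "shapes": [{"label": "fruit", "points": pts} for pts in shapes]}
            )
        )
        return path

    def test_square_inclusive_rasterization(self, tmp_path):
        square = [[0, 0], [10, 0], [10, 10], [0, 10]]
        mask, vertices = color.read_polygon_mask(self.write_annotation(tmp_path, [square]))
        assert mask.sum() == 121
        np.testing.assert_array_equal(vertices[0], square)
        # cross-check against brute-force point-in-polygon over every pixel
        for y in range(20):
            for x in range(20):
                assert mask[y, x] == point_in_polygon(x, y, square)

    def test_zero_area_polygon_rejected(self, tmp_path):
        degenerate = [[0, 0], [5, 5], [10, 10]]
        with pytest.raises(ValueError, match="zero-area"):
            color.read_polygon_mask(self.write_annotation(tmp_path, [degenerate]))

    def test_two_polygons_union(self, tmp_path):
        a = [[0, 0], [4, 0], [4, 4], [0, 4]]
        b = [[10, 10], [14, 10], [14, 14], [10, 14]]
        mask, _ = color.read_polygon_mask(self.write_annotation(tmp_path, [a, b]))
        assert mask.sum() == 50  # two inclusive 5×5 squares
        assert mask[2, 2] and mask[12, 12] and not mask[7, 7]


class TestObservationCsv:
    def test_append_creates_header_once(self, tmp_path):
        from tomaqual.simulate import render_fruit_image

        img, mask = render_fruit_image(np.array([0.6, 0.1, 0.3]), size=48, seed=1)
        obs = color.observe(img, mask)
        path = tmp_path / "observations.csv"
        color.append_observation_csv(path, "img1.png", obs)
        color.append_observation_csv(path, "img2.png", obs)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 3 and lines[0].startswith("image,")
        assert obs.maturity_level == 4
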