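import math

import numpy as np
import pytest
from skimage.draw import disk, ellipse

from cyanocount import morphology as morph
from cyanocount.errors import CompactnessWarning, ContractError
from cyanocount.segmentation import LabelField, connected_components


def disc_mask(radius, pad=3):
    n = 2 * (radius + pad) + 1
    mask = np.zeros((n, n), bool)
    rr, cc = disk((radius + pad, radius + pad), radius + 0.5)
    mask[rr, cc] = True
    return mask


def ellipse_mask(a, b, rotation=0.0, pad=4):
    n = 2 * (max(a, b) + pad) + 1
    mask = np.zeros((n, n), bool)
    rr, cc = ellipse(n // 2, n // 2, b + 0.5, a + 0.5, rotation=rotation)
    mask[rr, cc] = True
    return mask


class TestEccentricity:
    def test_disc_is_circle_limit(self):
        assert morph.eccentricity(disc_mask(20)) <= 0.1

    def test_line_segment_limit(self):
        line = np.zeros((3, 52), bool)
        line[1, 1:51] = True
        assert morph.eccentricity(line) >= 0.99

    def test_closed_form_ellipse(self):
        # semi-axes (10, 6): e = sqrt(1 - 36/100) = 0.8
        assert morph.eccentricity(ellipse_mask(10, 6)) == pytest.approx(
            0.8, abs=0.05
        )

    def test_single_pixel_defined_zero(self):
        assert morph.eccentricity(np.ones((1, 1), bool)) == 0.0

    def test_empty_component_rejected(self):
        with pytest.raises(ContractError):
            morph.eccentricity(np.zeros((3, 3), bool))

    @pytest.mark.parametrize("rot", [0.0, np.pi / 6, np.pi / 4, np.pi / 2])
    def test_rotation_robustness(self, rot):
        e0 = morph.eccentricity(ellipse_mask(14, 8, 0.0))
        e = morph.eccentricity(ellipse_mask(14, 8, rot))
        assert abs(e - e0) <= 0.05


class TestCompactness:
    def test_analytic_circle_is_one(self):
        r = 10.0
        assert morph.compactness(math.pi * r**2, 2 * math.pi * r) == (
            pytest.approx(1.0, abs=1e-12)
        )

    def test_analytic_square(self):
        s = 7.0
        assert morph.compactness(s**2, 4 * s) == pytest.approx(math.pi / 4)

    def test_algebraic_identity(self):
        assert morph.compactness(1.0, 2 * math.sqrt(math.pi)) == (
            pytest.approx(1.0)
        )

    def test_zero_perimeter_rejected(self):
        with pytest.raises(ContractError):
            morph.compactness(5.0, 0.0)

    def test_warns_above_bound(self):
        with pytest.warns(CompactnessWarning):
            morph.compactness(10.0, 2.0)


class TestConvexAreaSolidityExtent:
    def test_filled_square_equals_own_hull(self):
        sq = np.zeros((5, 5), bool)
        sq[1:4, 1:4] = True
        assert morph.convex_area(sq) == pytest.approx(9, abs=1)

    def test_l_tromino_hull_strictly_larger(self):
        tromino = np.zeros((4, 4), bool)
        tromino[1, 1] = tromino[2, 1] = tromino[2, 2] = True
        assert morph.convex_area(tromino) > 3

    @staticmethod
    def _monotone_chain_area(points):
        """Independent hull oracle: Andrew's monotone chain + shoelace."""
        pts = sorted(map(tuple, points))

        def half(seq):
            chain = []
            for p in seq:
                while len(chain) >= 2 and (
                    (chain[-1][0] - chain[-2][0]) * (p[1] - chain[-2][1])
                    - (chain[-1][1] - chain[-2][1]) * (p[0] - chain[-2][0])
                ) <= 0:
                    chain.pop()
                chain.append(p)
            return chain[:-1]

        hull = half(pts) + half(pts[::-1])
        area = 0.0
        for (x1, y1), (x2, y2) in zip(hull, hull[1:] + hull[:1]):
            area += x1 * y2 - x2 * y1
        return abs(area) / 2.0

    def test_c_arc_hull_against_point_set_oracle(self):
        # rasterized annulus sector spanning 270 degrees
        n = 41
        yy, xx = np.mgrid[:n, :n]
        r = np.hypot(yy - n // 2, xx - n // 2)
        ang = np.arctan2(yy - n // 2, xx - n // 2)
        mask = (r >= 10) & (r <= 15) & (np.abs(ang) <= 3 * np.pi / 4)
        area = mask.sum()
        ca = morph.convex_area(mask)
        assert ca >= 1.3 * area
        # independent oracle: brute-force hull of the pixel-corner points
        rows, cols = np.nonzero(mask)
        corners = np.concatenate([
            np.stack([rows + dr, cols + dc], axis=1)
            for dr in (0, 1) for dc in (0, 1)
        ])
        assert ca == pytest.approx(self._monotone_chain_area(corners),
                                   abs=1e-9)

    def test_filled_rectangle_extent_and_solidity(self):
        rect = np.zeros((8, 12), bool)
        rect[1:6, 2:10] = True
        assert morph.extent(rect.sum(), 5 * 8) == 1.0
        assert morph.solidity(rect.sum(), morph.convex_area(rect)) == 1.0

    def test_disc_extent_approaches_quarter_pi(self):
        mask = disc_mask(20, pad=0)
        assert morph.extent(mask.sum(), mask.shape[0] * mask.shape[1]) == (
            pytest.approx(math.pi / 4, abs=0.05)
        )

    def test_zero_denominators_rejected(self):
        with pytest.raises(ContractError):
            morph.solidity(3.0, 0.0)
        with pytest.raises(ContractError):
            morph.extent(3.0, 0.0)


class TestPerimeter:
    def test_disc_close_to_equal_area_circumference(self):
        mask = disc_mask(20)
        p = morph.perimeter(mask)
        circumference = 2 * math.pi * math.sqrt(mask.sum() / math.pi)
        assert p == pytest.approx(circumference, rel=0.05)

    def test_single_pixel_convention(self):
        assert morph.perimeter(np.ones((1, 1), bool)) == 1.0


class TestFeaturize:
    def _label_field(self, mask):
        return connected_components(mask, 8, 0)

    def test_empty_field(self):
        lf = self._label_field(np.zeros((5, 5), bool))
        assert morph.featurize(lf, 1.0) == []

    def test_single_disc_record(self):
        lf = self._label_field(disc_mask(20))
        (f,) = morph.featurize(lf, 0.5)
        assert f.eccentricity <= 0.1
        assert f.compactness == pytest.approx(1.0, abs=0.15)
        # corner hull of a rasterized disc exceeds its pixel count by
        # roughly half the perimeter, so solidity sits just below 1
        assert f.solidity == pytest.approx(1.0, abs=0.1)
        assert f.area_um2 == pytest.approx(f.area_px * 0.25)

    def test_record_order_matches_labels(self):
        mask = np.zeros((20, 20), bool)
        mask[1:4, 1:4] = True
        mask[10:16, 10:16] = True
        feats = morph.featurize(self._label_field(mask), 1.0)
        assert [f.label for f in feats] == [1, 2]
        assert feats[0].area_px == 9
        assert feats[1].area_px == 36

    def test_component_invariants_on_random_blobs(self, rng):
        mask = rng.random((80, 80)) > 0.6
        feats = morph.featurize(connected_components(mask, 8, 4), 1.0)
        assert feats
        for f in feats:
            assert 0 <= f.eccentricity <= 1
            # hull discretization tolerance
            assert f.area_px <= f.convex_area_px + 1
            assert f.extent <= 1.0 + 1e-12
            assert f.solidity <= 1.0 + 0.05

    def test_filament_vs_disc_feature_ordering(self):
        """Filamentous chains must score higher eccentricity and lower
        compactness than round unicells."""
        from cyanocount.synthdata import FilamentSpec, SceneSpec, generate_scene

        image, truth = generate_scene(SceneSpec(
            counts={"A": 5}, image_size=(400, 500),
            filament=FilamentSpec(cells_per_filament=(10.0, 0.0)),
            seed=4,
        ))
        lf = connected_components(truth.labels > 0, 8, 4)
        for f in morph.featurize(lf, 0.645):
            assert f.eccentricity >= 0.9
            assert f.compactness <= 0.65

    def test_scale_covariance(self):
        def raster(a, b):
            n = 2 * (a + 4) + 1
            mask = np.zeros((n, n), bool)
            rr, cc = ellipse(n // 2, n // 2, b, a)
            mask[rr, cc] = True
            return mask

        # base shape large enough that discretization bias (strongest for
        # small rasters) stays inside the 5 % covariance band
        small = raster(20, 12)
        large = raster(40, 24)
        fs = morph.featurize(self._label_field(small), 1.0)[0]
        fl = morph.featurize(self._label_field(large), 1.0)[0]
        assert fl.area_px == pytest.approx(4 * fs.area_px, rel=0.05)
        for name in ("eccentricity", "compactness", "solidity", "extent"):
            assert getattr(fl, name) == pytest.approx(
                getattr(fs, name), rel=0.05, abs=0.02
            )

    def test_single_pixel_component_capped(self):
        labels = np.zeros((4, 4), dtype=np.int32)
        labels[1, 1] = 1
        lf = LabelField(mask=labels > 0, labels=labels, n_components=1)
        with pytest.warns(CompactnessWarning):
            (f,) = morph.featurize(lf, 1.0)
        assert f.perimeter_px == 1.0
        assert f.eccentricity == 0.0
        assert f.compactness == pytest.approx(4 * math.pi)
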