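"""Feature extraction: geometry conventions, region-restricted texture
descriptors and the 54-entry vector contract."""

import numpy as np
import pytest

from qfuzzy.cells import InvalidCellError, SegmentedCell, rgb_to_gray
from qfuzzy.features import (
    FEATURE_NAMES,
    extract_features,
    mean_brightness,
    region_geometry,
)
from qfuzzy.texture import glcm_homogeneity, lbp_hf, local_extrema_count

from conftest import disk


def make_cell(nucleus, cytoplasm=None, intensity=None):
    shape = nucleus.shape
    if cytoplasm is None:
        cytoplasm = np.zeros(shape, bool)
        cytoplasm[0, 0] = True
    mask = np.zeros(shape, dtype=int)
    mask[cytoplasm] = 1
    mask[nucleus] = 2
    if intensity is None:
        intensity = np.full(shape, 128.0)
    return SegmentedCell(intensity=intensity, mask=mask)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

class TestRegionGeometry:
    def test_rectangle_area_and_aspect(self):
        nucleus = np.zeros((40, 40), bool)
        nucleus[10:20, 5:25] = True  # 10 rows tall, 20 cols wide
        geo = region_geometry(make_cell(nucleus))
        assert geo["A_n"] == 200
        assert geo["R_n"] == 2.0

    def test_disk_roundness_near_one(self):
        nucleus = disk((60, 60), (30, 30), 20)
        geo = region_geometry(make_cell(nucleus))
        assert 0.95 <= geo["N_roundness"] <= 1.05

    def test_ellipse_axes_match_moment_oracle(self):
        rr, cc = np.indices((70, 110))
        nucleus = ((rr - 35) / 10.0) ** 2 + ((cc - 55) / 20.0) ** 2 <= 1.0
        geo = region_geometry(make_cell(nucleus))
        assert geo["L_n"] == pytest.approx(40.0, rel=0.05)
        assert geo["D_n"] == pytest.approx(20.0, rel=0.05)
        # independent second-central-moment oracle: for a region with
        # covariance eigenvalues lam, the equivalent-ellipse axes are
        # 4*sqrt(lam) long
        ys, xs = np.nonzero(nucleus)
        cov = np.cov(np.stack([ys, xs]))
        lam = np.sort(np.linalg.eigvalsh(cov))
        assert geo["L_n"] == pytest.approx(4.0 * np.sqrt(lam[1]), rel=0.01)
        assert geo["D_n"] == pytest.approx(4.0 * np.sqrt(lam[0]), rel=0.01)

    def test_major_axis_not_shorter_than_minor(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            nucleus = np.zeros((30, 30), bool)
            r0, c0 = rng.integers(2, 12, 2)
            nucleus[r0 : r0 + rng.integers(3, 15), c0 : c0 + rng.integers(3, 15)] = True
            geo = region_geometry(make_cell(nucleus))
            assert geo["L_n"] >= geo["D_n"]

    def test_disk_roundness_approaches_one_monotonically(self):
        vals = []
        for r in (10, 20, 40):
            nucleus = disk((2 * r + 9, 2 * r + 9), (r + 4, r + 4), r)
            vals.append(region_geometry(make_cell(nucleus))["N_roundness"])
        assert vals[0] < vals[1] < vals[2] <= 1.0
        assert all(abs(v - 1.0) < 0.05 for v in vals)

    def test_disk_compactness_approaches_4pi(self):
        # compactness P^2/A of a disk is 4*pi in the continuum; the
        # chain-code perimeter estimator keeps rasterized disks within 15%
        for r in (10, 20, 40):
            region = disk((2 * r + 9, 2 * r + 9), (r + 4, r + 4), r)
            # whole-cell region is the disk itself (1-px token nucleus)
            mask = np.zeros(region.shape, int)
            mask[region] = 1
            mask[r + 4, r + 4] = 2
            cell = SegmentedCell(intensity=np.full(region.shape, 50.0), mask=mask)
            geo = region_geometry(cell)
            assert geo["C_cell"] == pytest.approx(4 * np.pi, rel=0.15)

    def test_nucleus_cytoplasm_ratio(self):
        nucleus = np.zeros((30, 30), bool)
        nucleus[5:10, 5:10] = True  # 25 px
        cyto = np.zeros((30, 30), bool)
        cyto[15:25, 15:25] = True  # 100 px
        geo = region_geometry(make_cell(nucleus, cyto))
        assert geo["R_cell"] == pytest.approx(0.25)

    def test_empty_regions_rejected(self):
        with pytest.raises(InvalidCellError):
            SegmentedCell(intensity=np.zeros((5, 5)), mask=np.zeros((5, 5), int))


# ---------------------------------------------------------------------------
# local extrema
# ---------------------------------------------------------------------------

class TestLocalExtrema:
    def test_constant_region_has_none(self):
        img = np.full((10, 10), 5.0)
        region = np.ones((10, 10), bool)
        assert local_extrema_count(img, region, "max") == 0
        assert local_extrema_count(img, region, "min") == 0

    def test_single_interior_peak(self):
        img = np.zeros((9, 9))
        img[4, 4] = 255.0
        region = np.ones((9, 9), bool)
        assert local_extrema_count(img, region, "max") == 1
        # its 8 neighbours tie with the rest of the flat field: no minima
        assert local_extrema_count(img, region, "min") == 0

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(11)
        img = rng.integers(0, 256, (20, 20)).astype(float)
        region = disk((20, 20), (10, 10), 8)

        def brute(mode):
            count = 0
            for r in range(20):
                for c in range(20):
                    if not region[r, c]:
                        continue
                    vals = []
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            if dr == dc == 0:
                                continue
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < 20 and 0 <= cc < 20 and region[rr, cc]:
                                vals.append(img[rr, cc])
                    if not vals:
                        continue
                    if mode == "max" and all(img[r, c] > v for v in vals):
                        count += 1
                    if mode == "min" and all(img[r, c] < v for v in vals):
                        count += 1
            return count

        assert local_extrema_count(img, region, "max") == brute("max")
        assert local_extrema_count(img, region, "min") == brute("min")

    def test_two_separated_peaks(self):
        img = np.zeros((12, 12))
        img[3, 3] = img[8, 8] = 9.0
        assert local_extrema_count(img, np.ones((12, 12), bool), "max") == 2


# ---------------------------------------------------------------------------
# GLCM homogeneity
# ---------------------------------------------------------------------------

class TestGlcmHomogeneity:
    def test_constant_region_is_one(self):
        assert glcm_homogeneity(np.full((8, 8), 37.0), np.ones((8, 8), bool)) == 1.0

    def test_checkerboard_is_half(self):
        board = (np.indices((16, 16)).sum(axis=0) % 2) * 255.0
        h = glcm_homogeneity(board, np.ones((16, 16), bool), levels=2, offset=(0, 1))
        assert h == pytest.approx(0.5)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        img = rng.integers(0, 256, (16, 16)).astype(float)
        region = disk((16, 16), (8, 8), 7)
        levels, offset = 8, (0, 1)

        # independent double-loop evaluation
        q = np.minimum((img * levels / 256).astype(int), levels - 1)
        counts = np.zeros((levels, levels))
        for r in range(16):
            for c in range(16):
                r2, c2 = r + offset[0], c + offset[1]
                if region[r, c] and r2 < 16 and c2 < 16 and region[r2, c2]:
                    counts[q[r, c], q[r2, c2]] += 1
                    counts[q[r2, c2], q[r, c]] += 1
        p = counts / counts.sum()
        expected = sum(
            p[i, j] / (1 + abs(i - j)) for i in range(levels) for j in range(levels)
        )
        assert glcm_homogeneity(img, region, levels, offset) == pytest.approx(
            expected, abs=1e-12
        )

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            img = rng.integers(0, 256, (10, 10)).astype(float)
            h = glcm_homogeneity(img, np.ones((10, 10), bool))
            assert 0.0 <= h <= 1.0


# ---------------------------------------------------------------------------
# brightness
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "values,expected",
    [(np.full(9, 37.0), 37.0), (np.array([10.0, 20.0]), 15.0)],
)
def test_mean_brightness(values, expected):
    img = np.zeros((3, 9))
    region = np.zeros((3, 9), bool)
    img[1, : values.size] = values
    region[1, : values.size] = True
    assert mean_brightness(img, region) == expected


def test_mean_brightness_random_matches_sum_oracle():
    rng = np.random.default_rng(2)
    img = rng.uniform(0, 255, (12, 12))
    region = disk((12, 12), (6, 6), 5)
    total = sum(img[r, c] for r, c in zip(*np.nonzero(region)))
    assert mean_brightness(img, region) == pytest.approx(total / region.sum())


def test_mean_brightness_empty_region_rejected():
    with pytest.raises(ValueError):
        mean_brightness(np.zeros((4, 4)), np.zeros((4, 4), bool))


# ---------------------------------------------------------------------------
# LBP-HF
# ---------------------------------------------------------------------------

class TestLbpHf:
    def test_length_is_38(self, textured_cell):
        vec = lbp_hf(textured_cell.intensity, textured_cell.cell_region)
        assert vec.shape == (38,)

    def test_constant_image_all_ones_bin(self):
        vec = lbp_hf(np.full((12, 12), 7.0), np.ones((12, 12), bool))
        # neighbour >= centre everywhere -> every pattern is all-ones
        assert vec[-2] == 1.0
        assert np.all(vec[:-2] == 0.0)
        assert vec[-1] == 0.0

    def test_rotation_invariance(self):
        rng = np.random.default_rng(13)
        img = rng.integers(0, 256, (32, 32)).astype(float)
        region = np.ones((32, 32), bool)
        v0 = lbp_hf(img, region)
        v90 = lbp_hf(np.rot90(img), np.rot90(region))
        assert np.allclose(v0, v90, atol=1e-6)

    def test_histogram_mass_totals_one(self, textured_cell):
        vec = lbp_hf(textured_cell.intensity, textured_cell.cell_region)
        # orbit DC components (u=0) carry each orbit's total mass
        dc = vec[: 35].reshape(7, 5)[:, 0]
        assert dc.sum() + vec[35:].sum() == pytest.approx(1.0)

    def test_too_small_region_rejected(self):
        with pytest.raises(ValueError):
            lbp_hf(np.zeros((2, 2)), np.ones((2, 2), bool))


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

class TestExtractFeatures:
    def test_schema_and_length(self, textured_cell):
        vec = extract_features(textured_cell)
        assert list(vec.index) == FEATURE_NAMES
        assert len(vec) == 54

    def test_deterministic(self, textured_cell):
        v1 = extract_features(textured_cell)
        v2 = extract_features(textured_cell)
        assert (v1.to_numpy() == v2.to_numpy()).all()

    def test_translation_invariance(self, textured_cell):
        pad = 8
        shifted = SegmentedCell(
            intensity=np.pad(textured_cell.intensity, ((pad, 0), (0, pad)),
                             constant_values=220.0),
            mask=np.pad(textured_cell.mask, ((pad, 0), (0, pad))),
        )
        v0 = extract_features(textured_cell).to_numpy()
        v1 = extract_features(shifted).to_numpy()
        assert (v0 == v1).all()

    def test_brightness_and_ratio_values(self, disk_cell):
        vec = extract_features(disk_cell)
        assert vec["B_n"] == 90.0
        assert vec["B_c"] == 160.0
        assert vec["H_n"] == 1.0  # constant nucleus
        a_n = disk_cell.nucleus.sum()
        a_cy = disk_cell.cytoplasm.sum()
        assert vec["R_cell"] == pytest.approx(a_n / a_cy)

    def test_rgb_conversion_uses_luma_weights(self):
        rgb = np.zeros((4, 4, 3))
        rgb[..., 0] = 100.0
        assert np.allclose(rgb_to_gray(rgb), 29.9)
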