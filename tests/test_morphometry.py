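"""Axial reformatting, contour extraction, areas, thickness, sharpness."""

import numpy as np
import pytest
from scipy.special import erf

from carotidcs.contours import Contour, LUMEN, OUTER_WALL
from carotidcs.morphometry import (
    AxialVolume,
    detect_plaque,
    equivalent_radius,
    extract_contours_auto,
    mean_sharpness,
    measure_vessel,
    polygon_area,
    reformat_axial,
    select_slices,
    sharpness,
    wall_metrics,
)
from oracles import (
    erf_edge_d2080_oracle,
    radial_profile_chain_oracle,
    regular_polygon_area_oracle,
)


def circle(r, n=256, cx=0.0, cy=0.0):
    th = 2 * np.pi * np.arange(n) / n
    return np.stack([cx + r * np.cos(th), cy + r * np.sin(th)], axis=1)


def make_axial(data, voxel=(0.3, 0.2, 0.2)):
    nz, ny, nx = data.shape
    origin = (-(nz - 1) / 2 * voxel[0], -(ny - 1) / 2 * voxel[1], -(nx - 1) / 2 * voxel[2])
    return AxialVolume(data=data, voxel_mm=voxel, origin_mm=origin)


class TestReformatAxial:
    def test_identity_grid_unchanged(self, rng):
        vol = rng.standard_normal((10, 12, 8))
        out = reformat_axial(vol, (0.5, 0.5, 0.5), target_voxel_mm=(0.5, 0.5, 0.5))
        assert out.data.shape == (8, 12, 10)
        assert np.allclose(out.data, vol.transpose(2, 1, 0), atol=1e-12)

    def test_constant_volume_exact(self):
        vol = np.full((9, 9, 9), 3.7)
        out = reformat_axial(vol, (0.625, 0.625, 1.4))
        assert np.allclose(out.data, 3.7, atol=1e-12)

    def test_linear_ramp_reproduced(self):
        """Trilinear resampling is exact on a linear intensity ramp."""
        nx, ny, nz = 11, 12, 13
        x = (np.arange(nx) - (nx - 1) / 2) * 0.6
        vol = np.broadcast_to(x[:, None, None], (nx, ny, nz)).copy()
        out = reformat_axial(vol, (0.6, 0.6, 0.6), target_voxel_mm=(0.2, 0.25, 0.3))
        x_out = out.origin_mm[2] + np.arange(out.data.shape[2]) * out.voxel_mm[2]
        expected = np.broadcast_to(x_out[None, None, :], out.data.shape)
        assert np.allclose(out.data, expected, atol=1e-10)

    def test_invalid_target_voxel(self):
        with pytest.raises(ValueError, match="positive"):
            reformat_axial(np.zeros((4, 4, 4)), (1, 1, 1), target_voxel_mm=(0, 1, 1))


class TestPolygonArea:
    def test_unit_square_and_orientation(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert polygon_area(sq) == pytest.approx(1.0)
        assert polygon_area(sq[::-1]) == pytest.approx(1.0)

    def test_regular_64gon_closed_form(self):
        assert polygon_area(circle(1.0, 64)) == pytest.approx(
            regular_polygon_area_oracle(64, 1.0), rel=1e-12
        )

    def test_self_intersection_rejected(self):
        bowtie = np.array([[0, 0], [1, 1], [1, 0], [0, 1]], dtype=float)
        with pytest.raises(ValueError, match="self-intersect"):
            polygon_area(bowtie)


class TestEquivalentRadius:
    @pytest.mark.parametrize(
        "area,expected", [(np.pi, 1.0), (0.0, 0.0), (100.0, 5.641895835477563)]
    )
    def test_values(self, area, expected):
        assert equivalent_radius(area) == pytest.approx(expected, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            equivalent_radius(-1.0)


class TestWallMetrics:
    def test_concentric_circles(self):
        m = wall_metrics(circle(3.0, 512), circle(4.0, 512))
        assert m["lumen_area"] == pytest.approx(np.pi * 9, rel=1e-4)
        assert m["wall_area"] == pytest.approx(np.pi * 7, rel=1e-4)
        assert m["wall_thickness"] == pytest.approx(1.0, abs=5e-4)
        assert m["wall_area"] + m["lumen_area"] == pytest.approx(m["outer_area"], rel=1e-14)

    def test_identical_contours_zero_wall(self):
        m = wall_metrics(circle(2.0), circle(2.0))
        assert m["wall_area"] == pytest.approx(0.0, abs=1e-12)
        assert m["wall_thickness"] == pytest.approx(0.0, abs=1e-12)

    def test_homogeneity_degree_one(self):
        m1 = wall_metrics(circle(3.0, 128), circle(4.0, 128))
        m2 = wall_metrics(circle(6.0, 128), circle(8.0, 128))
        assert m2["wall_thickness"] == pytest.approx(2 * m1["wall_thickness"], rel=1e-9)

    def test_containment_violation(self):
        with pytest.raises(ValueError, match="contained"):
            wall_metrics(circle(4.0), circle(3.0))


class TestSharpness:
    def test_ideal_step_edge(self):
        """A step sampled at 0.2 mm: the 20-80 span of one linear segment is
        0.6 of a step."""
        nx = 81
        x = (np.arange(nx) - 40) * 0.2
        img = (x >= 0.05).astype(float)[None, None, :] * np.ones((1, 5, 1))
        vol = make_axial(np.broadcast_to(img, (1, 5, nx)).copy())
        res = sharpness(vol, 0, (0.0, 0.0), 0.0, half_length_mm=3.0, step_mm=0.2)
        assert res.d_20_80_mm == pytest.approx(0.6 * 0.2, rel=1e-6)
        assert res.sharpness_per_mm == pytest.approx(1 / 0.12, rel=1e-6)

    def test_erf_edge_oracle(self):
        sigma = 0.5
        nx, ny = 121, 15
        x = (np.arange(nx) - 60) * 0.2
        prof = 0.5 * (1 + erf(x / (sigma * np.sqrt(2))))
        data = np.broadcast_to(prof[None, None, :], (1, ny, nx)).copy()
        res = sharpness(make_axial(data), 0, (0.0, 0.0), 0.0)
        assert res.d_20_80_mm == pytest.approx(erf_edge_d2080_oracle(sigma), rel=0.02)

    def test_monotone_in_blur(self):
        vals = []
        for sigma in (0.3, 0.5, 0.8, 1.2):
            nx = 121
            x = (np.arange(nx) - 60) * 0.2
            prof = 0.5 * (1 + erf(x / (sigma * np.sqrt(2))))
            data = np.broadcast_to(prof[None, None, :], (1, 9, nx)).copy()
            vals.append(sharpness(make_axial(data), 0, (0.0, 0.0), 0.0).sharpness_per_mm)
        assert all(a > b for a, b in zip(vals[:-1], vals[1:]))

    def test_intensity_rescaling_invariance(self):
        nx = 121
        x = (np.arange(nx) - 60) * 0.2
        prof = 0.5 * (1 + erf(x / 0.7))
        data = np.broadcast_to(prof[None, None, :], (1, 9, nx)).copy()
        a = sharpness(make_axial(data), 0, (0.0, 0.0), 0.0)
        b = sharpness(make_axial(5.0 * data + 2.0), 0, (0.0, 0.0), 0.0)
        assert a.d_20_80_mm == pytest.approx(b.d_20_80_mm, rel=1e-12)

    def test_edge_not_bracketed(self):
        data = np.ones((1, 9, 21))
        with pytest.raises(ValueError, match="edge not bracketed"):
            sharpness(make_axial(data), 0, (0.0, 0.0), 0.0)

    def test_phantom_intrinsic_sharpness_matches_1d_chain_oracle(
        self, spec_default, phantom_default
    ):
        """The measured grid-aligned edge profile of the rendered phantom
        matches an independent 1-D model of the rendering + interpolation."""
        images, geom, _ = phantom_default
        ax = reformat_axial(
            np.abs(images["t1w"]),
            spec_default.voxel_mm,
            x_range_mm=(-12, 12),
            y_range_mm=(-8, 8),
            z_range_mm=(spec_default.bifurcation_z_mm - 8, spec_default.bifurcation_z_mm + 8),
        )
        sl = ax.slice_of_z(spec_default.bifurcation_z_mm - 5.0)
        res = sharpness(ax, sl, (3.0, 0.0), 0.0)
        t = np.arange(-3.0, 3.0 + 0.025, 0.05)
        prof = radial_profile_chain_oracle(3.0 + t)
        pn = (prof - prof.min()) / (prof.max() - prof.min())
        i8 = np.argmax(pn >= 0.8)
        i2 = np.flatnonzero(pn[: i8 + 1] <= 0.2)[-1]
        p2 = t[i2] + (0.2 - pn[i2]) / (pn[i2 + 1] - pn[i2]) * 0.05
        p8 = t[i8 - 1] + (0.8 - pn[i8 - 1]) / (pn[i8] - pn[i8 - 1]) * 0.05
        assert res.d_20_80_mm == pytest.approx(p8 - p2, rel=0.10)


class TestSelectSlices:
    def test_standard_windows(self):
        w = select_slices(200, bifurcation_index=100, dz_mm=0.3)
        assert w["CCA"] == [81, 82, 83, 84, 85]
        assert w["ICA"] == [115, 116, 117, 118, 119]
        assert w["ECA"] == w["ICA"]

    def test_zero_offset_abuts_bifurcation(self):
        w = select_slices(50, bifurcation_index=25, dz_mm=0.3, offset_mm=0.0)
        assert w["CCA"] == [23, 24, 25, 26, 27]

    def test_out_of_range(self):
        with pytest.raises(ValueError, match="outside"):
            select_slices(30, bifurcation_index=5, dz_mm=0.3)


class TestDetectPlaque:
    def test_threshold_inclusive(self):
        flags = detect_plaque(np.array([1.5, 1.49, 2.0, 0.0]))
        assert flags.tolist() == [True, False, True, False]

    def test_empty(self):
        assert detect_plaque(np.array([])).size == 0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            detect_plaque(np.array([-0.1]))


class TestExtractContours:
    def test_scale_invariance(self, spec_default, phantom_default):
        images, geom, _ = phantom_default
        ax = reformat_axial(
            np.abs(images["t1w"]), spec_default.voxel_mm,
            x_range_mm=(-9, 9), y_range_mm=(-9, 9), z_range_mm=(-6, -3),
        )
        hints = {1: [("CCA", 0.0, 0.0, 3.0)]}
        l1, o1 = extract_contours_auto(ax, [1], hints)
        ax2 = AxialVolume(data=2.0 * ax.data, voxel_mm=ax.voxel_mm, origin_mm=ax.origin_mm)
        l2, o2 = extract_contours_auto(ax2, [1], hints)
        assert np.allclose(l1.get(1, "CCA").vertices, l2.get(1, "CCA").vertices, atol=1e-9)

    def test_constant_slice_flagged_not_fabricated(self):
        vol = make_axial(np.zeros((3, 40, 40)))
        lum, out = extract_contours_auto(vol, [1], {1: [("CCA", 0.0, 0.0, 2.0)]})
        assert len(lum) == 0 and len(out) == 0

    def test_area_additivity_exact(self, spec_default, phantom_default):
        images, geom, _ = phantom_default
        ax = reformat_axial(
            np.abs(images["t1w"]), spec_default.voxel_mm,
            x_range_mm=(-9, 9), y_range_mm=(-9, 9), z_range_mm=(-6, -3),
        )
        hints = {i: [("CCA", 0.0, 0.0, 3.0)] for i in range(ax.n_slices)}
        lum, out = extract_contours_auto(ax, list(hints), hints)
        assert len(lum) == ax.n_slices
        for lc in lum:
            m = wall_metrics(lc, out.get(lc.slice_index, "CCA"))
            # wall + lumen equals the outer polygon area identically
            assert m["wall_area"] + m["lumen_area"] == pytest.approx(m["outer_area"], abs=1e-12)
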