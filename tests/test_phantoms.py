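"""Phantom generators: spheres, shells, electrodes, ROIs, dipoles, coil."""

import numpy as np
import pytest

from bemamr import (
    CoilSpec,
    ShellSpec,
    make_dipole_cluster,
    make_figure8_coil,
    make_icosphere,
    make_midlayer_roi,
    make_multishell,
    pick_electrode_patch,
    three_shell_specs,
)
from bemamr.io import read_model_bundle, read_surface, write_model_bundle, write_surface
from bemamr.phantoms import (
    FOURTEEN_TISSUE_CONDUCTIVITIES,
    SEVEN_TISSUE_CONDUCTIVITIES,
    focal_ring_montage,
)


class TestIcosphere:
    @pytest.mark.parametrize("n,facets", [(0, 20), (1, 80), (3, 1280)])
    def test_facet_counts(self, n, facets):
        assert make_icosphere(1.0, n).n_facets == facets

    def test_vertices_on_radius(self):
        s = make_icosphere(0.07, 2)
        np.testing.assert_allclose(
            np.linalg.norm(s.vertices, axis=1), 0.07, rtol=1e-12
        )

    def test_area_close_to_sphere(self):
        from bemamr import compute_geometry

        s = make_icosphere(0.1, 4)
        assert compute_geometry(s).areas.sum() == pytest.approx(
            4 * np.pi * 0.01, rel=5e-3
        )

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            make_icosphere(-1.0, 1)
        with pytest.raises(ValueError):
            make_icosphere(1.0, -1)


class TestMultishell:
    def test_contrast_from_adjacent_conductivities(self):
        model = make_multishell(three_shell_specs(), 1)
        sl = model.surface_slice(1)
        expected = (0.0042 - 0.33) / (0.0042 + 0.33)
        np.testing.assert_allclose(model.K[sl], expected)
        # outermost sees air
        np.testing.assert_allclose(model.K[model.surface_slice(2)], 1.0)

    def test_equal_conductivities_zero_contrast(self):
        model = make_multishell([ShellSpec(0.1, "s", 0.4)], 1)
        model.sigma_out[:] = 0.4
        model.rebuild()
        np.testing.assert_allclose(model.K, 0.0)

    def test_nonincreasing_radii_rejected(self):
        shells = [ShellSpec(0.1, "a", 0.3), ShellSpec(0.09, "b", 0.3)]
        with pytest.raises(ValueError, match="increasing"):
            make_multishell(shells, 1)

    def test_conductivity_presets_ship_verbatim(self):
        assert len(FOURTEEN_TISSUE_CONDUCTIVITIES) == 13
        assert FOURTEEN_TISSUE_CONDUCTIVITIES["Skin"] == 0.1700
        assert FOURTEEN_TISSUE_CONDUCTIVITIES["Ventricles"] == 1.6540
        assert FOURTEEN_TISSUE_CONDUCTIVITIES["Cortical bone"] == 0.0064
        assert SEVEN_TISSUE_CONDUCTIVITIES["Gray matter"] == 0.2750
        # the composite 7-tissue values are thickness-weighted averages
        skin = (
            0.2 * FOURTEEN_TISSUE_CONDUCTIVITIES["Skin"]
            + 0.4 * FOURTEEN_TISSUE_CONDUCTIVITIES["Fat"]
            + 0.4 * FOURTEEN_TISSUE_CONDUCTIVITIES["Muscle"]
        )
        assert SEVEN_TISSUE_CONDUCTIVITIES["Skin"] == pytest.approx(skin, abs=5e-4)
        # a model built from a preset loads without error
        shells = [
            ShellSpec(0.08, "Gray matter", SEVEN_TISSUE_CONDUCTIVITIES["Gray matter"]),
            ShellSpec(0.09, "Bone", SEVEN_TISSUE_CONDUCTIVITIES["Bone"]),
            ShellSpec(0.1, "Skin", SEVEN_TISSUE_CONDUCTIVITIES["Skin"]),
        ]
        model = make_multishell(shells, 1)
        assert model.n_facets == 240


class TestElectrodePatch:
    def test_radius_larger_than_sphere_selects_all(self):
        s = make_icosphere(0.1, 2)
        sel = pick_electrode_patch(s, np.array([0, 0, 0.1]), 1.0)
        assert len(sel) == s.n_facets

    def test_focal_ring_disjoint(self):
        s = make_icosphere(0.1, 4)
        montage = focal_ring_montage(s, np.array([0, 0, 0.1]))
        all_ids = np.concatenate(list(montage.values()))
        assert len(montage) == 5
        assert len(all_ids) == len(np.unique(all_ids))

    def test_patch_area_matches_spherical_cap(self):
        from bemamr import compute_geometry

        R, r_e = 0.1, 0.02
        s = make_icosphere(R, 4)
        geo = compute_geometry(s)
        sel = pick_electrode_patch(s, np.array([0, 0, R]), r_e)
        # chord radius r_e -> cap height h = R - sqrt(R^2 - r_e^2)
        h = R - np.sqrt(R**2 - r_e**2)
        cap = 2 * np.pi * R * h
        assert geo.areas[sel].sum() == pytest.approx(cap, rel=0.15)

    def test_invalid_radius(self):
        s = make_icosphere(0.1, 1)
        with pytest.raises(ValueError):
            pick_electrode_patch(s, np.array([0, 0, 0.1]), -1.0)


class TestMidlayerRoi:
    def test_concentric_spheres_midpoint_radius(self):
        inner = make_icosphere(0.07, 3)
        outer = make_icosphere(0.08, 3)
        roi = make_midlayer_roi(inner, outer, np.array([0, 0, 0.08]), 0.02)
        r = np.linalg.norm(roi.points, axis=1)
        np.testing.assert_allclose(r, 0.075, rtol=1e-2)

    def test_all_points_within_radius(self):
        inner = make_icosphere(0.07, 3)
        outer = make_icosphere(0.08, 3)
        target = np.array([0, 0, 0.075])
        roi = make_midlayer_roi(inner, outer, target, 0.02)
        assert np.linalg.norm(roi.points - target, axis=1).max() <= 0.02

    def test_density_comparable_to_nodal_density(self):
        inner = make_icosphere(0.07, 3)
        outer = make_icosphere(0.08, 3)
        target = np.array([0, 0, 0.075])
        roi = make_midlayer_roi(inner, outer, target, 0.02)
        # outer vertices whose midlayer point lands in the ROI sphere
        n_nodes = np.sum(
            np.linalg.norm(0.9375 * outer.vertices - target, axis=1) <= 0.02
        )
        assert n_nodes / 2 <= len(roi) <= n_nodes * 2


class TestDipoleCluster:
    def test_moment_surface_density(self):
        inner = make_icosphere(0.07, 5)
        outer = make_icosphere(0.08, 5)
        cl = make_dipole_cluster(
            inner, outer, np.array([0, 0, 0.075]), cluster_radius=1e-2
        )
        # 1 nA*m per mm^2: a dipole representing 1 mm^2 carries 1 nA*m
        moments = np.linalg.norm(cl.moments, axis=1)
        areas_mm2 = moments / 1e-9  # invert the constant
        # represented areas sum close to the (outer-surface) patch area
        patch = np.pi * 1e-2**2 * (0.08 / 0.075) ** 2
        assert areas_mm2.sum() * 1e-6 == pytest.approx(patch, rel=0.35)

    def test_midpoints_within_cluster_radius(self):
        inner = make_icosphere(0.07, 3)
        outer = make_icosphere(0.08, 3)
        target = np.array([0, 0, 0.075])
        cl = make_dipole_cluster(inner, outer, target, cluster_radius=8e-3)
        mids = 0.5 * (cl.sources + cl.sinks)
        assert np.linalg.norm(mids - target, axis=1).max() <= 8e-3

    def test_flat_patch_total_moment(self):
        """On a locally flat patch the summed vector moment approximates
        (patch area x moment density) along the local normal."""
        inner = make_icosphere(0.07, 4)
        outer = make_icosphere(0.08, 4)
        target = np.array([0, 0, 0.075])
        cl = make_dipole_cluster(inner, outer, target, cluster_radius=4e-3)
        total = cl.moments.sum(axis=0)
        mids = 0.5 * (cl.sources + cl.sinks)
        rep_area = np.linalg.norm(cl.moments, axis=1).sum() / 1e-3
        expected = 1e-3 * rep_area * np.array([0, 0, 1.0])
        np.testing.assert_allclose(total, expected, rtol=5e-2, atol=5e-2 * np.linalg.norm(expected))

    def test_no_support_rejected(self):
        inner = make_icosphere(0.07, 2)
        outer = make_icosphere(0.08, 2)
        with pytest.raises(ValueError, match="support"):
            make_dipole_cluster(inner, outer, np.array([0, 0, 0.2]), 1e-3)


class TestFigure8Coil:
    def _coil(self, **kw):
        surf = make_icosphere(0.1, 3)
        args = dict(
            loop_radius=0.027,
            turns=1,
            segments_per_loop=360,
            standoff=0.01,
            target=np.array([0, 0, 0.1]),
            surface=surf,
        )
        args.update(kw)
        return make_figure8_coil(**args), surf

    def test_segment_count(self):
        coil, _ = self._coil()
        assert len(coil.midpoints) == 720
        coil2, _ = self._coil(turns=3)
        assert len(coil2.midpoints) == 2160

    def test_loops_close(self):
        coil, _ = self._coil()
        seg = coil.directions * coil.lengths[:, None]
        for half in (seg[:360], seg[360:720]):
            closure = np.linalg.norm(half.sum(axis=0))
            assert closure <= 1e-9 * coil.lengths[:360].sum()

    def test_peak_didt_printed_value(self):
        coil = CoilSpec(
            np.zeros((1, 3)), np.array([[1.0, 0, 0]]), np.array([1.0]), I0=5e3, f=3e3
        )
        # 2 pi f I0 in kA/ms, printed as 94 at two significant figures
        assert coil.peak_didt / 1e6 == pytest.approx(94, abs=0.5)

    def test_standoff_respected(self):
        coil, surf = self._coil()
        from scipy.spatial import cKDTree

        d, _ = cKDTree(surf.vertices).query(coil.midpoints)
        assert d.min() >= 0.01 - 1e-9

    def test_too_few_segments_rejected(self):
        with pytest.raises(ValueError):
            self._coil(segments_per_loop=4)


class TestIO:
    @pytest.mark.parametrize("fmt", ["stl", "ply", "off"])
    def test_surface_roundtrip(self, tmp_path, fmt):
        s = make_icosphere(0.05, 1)
        p = tmp_path / f"s.{fmt}"
        write_surface(s, p)
        s2 = read_surface(p)
        # formats may store float32; geometry must survive to that precision
        tri1 = np.sort(s.vertices[s.facets].reshape(-1, 3), axis=0)
        tri2 = np.sort(s2.vertices[s2.facets].reshape(-1, 3), axis=0)
        np.testing.assert_allclose(tri1, tri2, atol=1e-6)

    def test_bundle_roundtrip(self, tmp_path):
        from bemamr import make_multishell

        model = make_multishell(three_shell_specs(), 1)
        model.electrodes = {"e": np.array([3, 5])}
        write_model_bundle(model, tmp_path / "bundle")
        model2 = read_model_bundle(tmp_path / "bundle")
        assert model2.n_facets == model.n_facets
        np.testing.assert_allclose(model2.sigma_in, model.sigma_in)
        np.testing.assert_array_equal(model2.electrodes["e"], [3, 5])
        np.testing.assert_allclose(model2.centroids, model.centroids, atol=1e-6)
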