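"""Synthetic-cohort generation: geometry sampling, meshing, rasterization
and the analytic ground-truth correspondence maps."""

import dataclasses

import numpy as np
import pytest
import scipy.ndimage as ndi

from grom import cohort as co
from grom.fem import PIAL, VENTRICLE, boundary_facets


def _flat_params(**over):
    base = dict(subject_id="t", group="healthy", R0=60.0,
                fold_amps=np.zeros(6), fold_phases=np.zeros(6),
                vent_center=np.zeros(2), vent_axes=np.array([8.0, 8.0]), seed=0)
    base.update(over)
    return co.GeometryParams(**base)


class TestSampling:
    def test_sampling_is_deterministic(self):
        spec = co.CohortSpec(n_healthy=2, n_inph=1, master_seed=7)
        a = co.sample_cohort(spec)
        b = co.sample_cohort(spec)
        for pa, pb in zip(a, b):
            assert pa.to_dict() == pb.to_dict()

    def test_full_scale_cohort_composition(self):
        """A 70 + 31 draw mirrors the clinical dataset structure: 101
        subjects, 31 flagged iNPH-like with enlarged ventricles."""
        spec = co.CohortSpec(n_healthy=70, n_inph=31, master_seed=5)
        cohort = co.sample_cohort(spec)
        assert len(cohort) == 101
        inph = [p for p in cohort if p.group == "inph"]
        assert len(inph) == 31
        assert all(np.all((p.vent_axes >= 14) & (p.vent_axes <= 22)) for p in inph)
        healthy = [p for p in cohort if p.group == "healthy"]
        assert all(np.all((p.vent_axes >= 6) & (p.vent_axes <= 10))
                   for p in healthy)

    def test_sampled_geometries_remain_annular(self, tiny_cohort):
        """Dense angular scan: the pial curve clears the ventricle everywhere."""
        theta = np.linspace(0, 2 * np.pi, 10_000, endpoint=False)
        for p in tiny_cohort:
            outer = co.outer_radius_about_center(p, theta)
            vent = co.ventricle_radius(p, theta)
            assert np.min(outer) - np.max(vent) > 0
            assert np.min(outer - vent) > 0

    def test_invalid_fold_amplitudes_rejected(self):
        with pytest.raises(ValueError, match="star-shaped"):
            _flat_params(fold_amps=np.full(6, 0.06))


class TestBoundaryCurves:
    def test_unfolded_outer_radius_is_constant(self):
        p = _flat_params()
        theta = np.linspace(0, 2 * np.pi, 50)
        assert np.allclose(co.boundary_radius(p, theta, "outer"), 60.0)

    def test_single_mode_peak_value(self):
        amps = np.zeros(6)
        amps[0] = 0.04  # k=3 mode, phase 0
        p = _flat_params(fold_amps=amps)
        assert co.boundary_radius(p, 0.0, "outer") == pytest.approx(1.04 * 60.0)

    def test_circular_ventricle_radius(self):
        p = _flat_params(vent_axes=np.array([7.0, 7.0]))
        theta = np.linspace(0, 2 * np.pi, 37)
        assert np.allclose(co.boundary_radius(p, theta, "ventricle"), 7.0)


class TestMeshing:
    def test_boundary_markers_cover_entire_boundary(self, coarse_mesh):
        """Every topological boundary facet carries exactly one marker."""
        topo = {tuple(sorted(f)) for f in boundary_facets(coarse_mesh.cells)}
        marked = {tuple(sorted(f)) for f in coarse_mesh.facets}
        assert topo == marked
        assert set(np.unique(coarse_mesh.facet_markers)) == {PIAL, VENTRICLE}

    def test_mesh_area_matches_boundary_quadrature(self, tiny_cohort):
        p = tiny_cohort[0]
        exact = co.analytic_area(p)
        mesh = co.build_mesh(p, 1.5)
        assert mesh.area() == pytest.approx(exact, rel=0.01)

    def test_refinement_improves_area(self, tiny_cohort):
        p = tiny_cohort[1]
        exact = co.analytic_area(p)
        err = [abs(co.build_mesh(p, h).area() - exact) for h in (3.0, 1.5)]
        assert err[1] < err[0]

    def test_node_count_scales_with_h(self, tiny_cohort):
        p = tiny_cohort[0]
        n3 = co.build_mesh(p, 3.0).n_nodes
        n15 = co.build_mesh(p, 1.5).n_nodes
        assert 2.5 < n15 / n3 < 6.0  # ~ area / h^2


class TestRasterization:
    def test_intensity_zero_in_ventricle_and_background(self, tiny_cohort,
                                                        tiny_spec):
        p = tiny_cohort[0]
        img = co.rasterize(p, tiny_spec)
        centre = img.sample(p.vent_center[None, :])
        assert centre[0] == pytest.approx(0.0, abs=1e-12)
        corner = img.data[0, 0]
        assert corner == 0.0

    def test_intensity_near_one_just_inside_pial_surface(self, tiny_cohort,
                                                         tiny_spec):
        p = tiny_cohort[0]
        img = co.rasterize(p, tiny_spec)
        theta = 0.7
        R = co.outer_radius_about_center(p, np.array([theta]))[0]
        pt = p.vent_center + (R - 2.0 * tiny_spec.voxel_size) * np.array(
            [np.cos(theta), np.sin(theta)])
        assert img.sample(pt[None, :])[0] > 0.93

    def test_image_support_area_matches_mesh_area(self, tiny_cohort, tiny_spec,
                                                  coarse_mesh):
        p = tiny_cohort[0]
        img = co.rasterize(p, tiny_spec)
        vox_area = tiny_spec.voxel_size ** 2
        support = float(np.sum(img.data > 0.2) * vox_area)
        assert support == pytest.approx(coarse_mesh.area(), rel=0.02)

    def test_mesh_nodes_lie_in_image_support(self, tiny_cohort, tiny_spec,
                                             coarse_mesh):
        """Mesh/image consistency with one-voxel boundary tolerance."""
        img = co.rasterize(tiny_cohort[0], tiny_spec)
        dilated = ndi.maximum_filter(img.data, size=3)
        ij = np.round(img.world_to_index(coarse_mesh.nodes)).astype(int)
        assert np.all(dilated[ij[:, 0], ij[:, 1]] > 0)

    def test_field_of_view_guard(self, tiny_cohort):
        small = co.CohortSpec(n_healthy=2, n_inph=0, master_seed=1,
                              image_shape=(64, 64))
        with pytest.raises(ValueError, match="field of view"):
            co.rasterize(tiny_cohort[0], small)


class TestAnalyticMap:
    def test_identity_map_has_zero_displacement(self, tiny_cohort, tiny_spec):
        p = tiny_cohort[0]
        field = co.analytic_map(p, p, tiny_spec)
        assert np.max(np.abs(field.displacement)) < 1e-9

    def test_ventricle_boundary_maps_onto_ventricle_boundary(self, geom_pair):
        src, dst = geom_pair
        theta = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        rv = co.ventricle_radius(src, theta)
        pts = src.vent_center + np.column_stack(
            [rv * np.cos(theta), rv * np.sin(theta)])
        mapped = co.analytic_map_points(src, dst, pts)
        d = mapped - dst.vent_center
        r_m = np.linalg.norm(d, axis=1)
        th_m = np.arctan2(d[:, 1], d[:, 0])
        assert np.max(np.abs(r_m - co.ventricle_radius(dst, th_m))) < 0.1

    def test_map_jacobian_positive_throughout_annulus(self, geom_pair,
                                                      tiny_spec):
        from grom.transfer import numerical_point_map_jacobian

        src, dst = geom_pair
        grid = tiny_spec.affine()
        nx, ny = tiny_spec.image_shape
        ii, jj = np.meshgrid(np.arange(0, nx, 2), np.arange(0, ny, 2),
                             indexing="ij")
        pts = (np.column_stack([ii.ravel(), jj.ravel()]) @ grid[:2, :2].T
               + grid[:2, 2])
        _, rho = co.annular_coordinates(src, pts)
        inside = (rho > 0.02) & (rho < 0.98)
        J = numerical_point_map_jacobian(
            lambda q: co.analytic_map_points(src, dst, q), pts[inside])
        assert np.all(np.linalg.det(J) > 0)

    def test_forward_backward_composition_is_identity(self, geom_pair,
                                                      tiny_spec):
        """Grid-sampled fields a->b then b->a return interior voxels to
        within 0.2 mm (interpolation is the only error source)."""
        src, dst = geom_pair
        fwd = co.analytic_map(src, dst, tiny_spec)
        back = co.analytic_map(dst, src, tiny_spec)
        from grom.imaging import apply_deformation

        nx, ny = tiny_spec.image_shape
        A = tiny_spec.affine()
        ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        pts = (np.column_stack([ii.ravel(), jj.ravel()]) @ A[:2, :2].T
               + A[:2, 2])
        _, rho = co.annular_coordinates(src, pts)
        interior = (rho > 0.1) & (rho < 0.9)
        roundtrip = apply_deformation(back, apply_deformation(fwd, pts[interior]))
        resid = np.linalg.norm(roundtrip - pts[interior], axis=1)
        assert np.max(resid) < 0.2

    def test_inph_ventricles_are_larger(self, tiny_cohort):
        h_r = np.mean([p.vent_axes for p in tiny_cohort if p.group == "healthy"])
        i_r = np.mean([p.vent_axes for p in tiny_cohort if p.group == "inph"])
        assert i_r > h_r + 3.0


def test_manifest_roundtrip(tmp_path, tiny_cohort, tiny_spec):
    path = tmp_path / "manifest.json"
    co.save_manifest(tiny_cohort, tiny_spec, path)
    cohort2, spec2 = co.load_manifest(path)
    assert spec2 == tiny_spec
    for a, b in zip(tiny_cohort, cohort2):
        assert a.to_dict() == b.to_dict()
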