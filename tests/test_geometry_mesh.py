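"""Geometry generators: volumes, watertightness, tags, quality, symmetry."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from fontanflow import (GeometrySpec, MeshSizing, Mesh, MeshError,
                        apply_boundary_layer, make_frustum,
                        make_pipe, mesh_quality, obstacle_surface_area)


class TestPipe:
    def test_volume_matches_cylinder(self, verification_pipe):
        analytic = np.pi * 0.955 ** 2 * 8.0
        err = abs(verification_pipe.total_volume() - analytic) / analytic
        assert err < 0.02

    def test_refinement_monotonicity(self, coarse_sizing):
        coarse = make_pipe(0.955, 8.0, coarse_sizing)
        fine = make_pipe(0.955, 8.0, coarse_sizing.scaled(0.5))
        assert fine.n_nodes > coarse.n_nodes

    def test_watertight_and_tagged(self, verification_pipe):
        m = verification_pipe
        assert m.unmatched_boundary_edges() == 0
        assert set(m.tags) == {"inlet", "outlet", "wall"}
        m.validate()

    def test_degenerate_sizing_rejected(self):
        sz = MeshSizing(h_iso=1.0, h_tubing_surface=0.9,
                        h_impeller_surface=0.9, h_strut_surface=0.9)
        with pytest.raises(ValueError, match="too coarse"):
            make_pipe(0.3, 2.0, sz)

    def test_frustum_volume(self, coarse_sizing):
        r0, r1, L = 0.8, 0.5, 4.0
        m = make_frustum(r0, r1, L, coarse_sizing.scaled(0.4))
        analytic = np.pi * L / 3.0 * (r0 ** 2 + r0 * r1 + r1 ** 2)
        assert abs(m.total_volume() - analytic) / analytic < 0.02


class TestJunction:
    def test_blank_tags(self, blank_junction):
        assert set(blank_junction.tags) == {
            "inlet_svc", "inlet_ivc", "outlet_rpa", "outlet_lpa",
            "wall_housing"}

    def test_watertight(self, blank_junction):
        blank_junction.validate()
        assert blank_junction.unmatched_boundary_edges() == 0

    def test_quality_gate(self, blank_junction):
        q = mesh_quality(blank_junction)
        assert q["min_dihedral_deg"] > 10.0
        assert q["mean_aspect_ratio"] < 4.0

    def test_mirror_symmetry(self, blank_junction):
        """The left/right-mirrored geometry has the reflected vertex set."""
        pts = blank_junction.nodes
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        d, _ = cKDTree(pts).query(mirrored)
        assert d.max() < 1e-9

    def test_port_disc_areas(self, blank_junction):
        areas, _ = blank_junction.face_areas_normals()
        disc = np.pi * 0.955 ** 2
        for tag in ("inlet_svc", "inlet_ivc", "outlet_rpa", "outlet_lpa"):
            a = areas[blank_junction.faces_of(tag)].sum()
            assert abs(a - disc) / disc < 0.08

    def test_volume_plausible(self, blank_junction):
        # four arms plus the housing bulge; crude analytic bracket
        v = blank_junction.total_volume()
        assert 55.0 < v < 85.0

    def test_obstacle_spec_validation(self):
        with pytest.raises(ValueError, match="intersects"):
            GeometrySpec(obstacle="biconical", hub_radius=1.66,
                         blade_height=0.01)
        with pytest.raises(ValueError, match="blade_height"):
            GeometrySpec(obstacle="biconical", blade_height=0.7)
        with pytest.raises(ValueError, match="arm_length"):
            GeometrySpec(arm_length=3.0)
        with pytest.raises(ValueError, match="strut_count"):
            GeometrySpec(strut_count=3)

    def test_blade_height_increases_wetted_area(self):
        tall = obstacle_surface_area(GeometrySpec(
            obstacle="biconical", blade_height=0.162, fillets=True))
        short = obstacle_surface_area(GeometrySpec(
            obstacle="biconical", blade_height=0.109, fillets=False))
        blank = obstacle_surface_area(GeometrySpec())
        assert blank == 0.0
        assert tall > short > 0.0


class TestBoundaryLayerSizing:
    @pytest.mark.parametrize("n,expected", [(3, 0.2 / 8), (1, 0.1), (2, 0.05)])
    def test_graded_target_size(self, n, expected):
        """Innermost near-wall target size is h_iso / 2**n."""
        from fontanflow.geometry import JunctionDomain
        sz = MeshSizing(bl_layers_central=n, bl_layers_peripheral=n)
        dom = JunctionDomain(GeometrySpec())
        # a point just off the housing wall at the junction center height
        p = np.array([[1.7 - 0.2 * expected, 0.0, 0.0]])
        s = dom.volume_size(p, sz)
        assert s[0] == pytest.approx(expected)

    def test_zero_layers_noop_with_warning(self, tiny_pipe):
        sz = MeshSizing(bl_layers_central=0, bl_layers_peripheral=0)
        with pytest.warns(UserWarning, match="no-op"):
            out = apply_boundary_layer(tiny_pipe, sz)
        assert out is tiny_pipe

    def test_regenerates_with_more_nodes(self, coarse_sizing):
        m = make_pipe(0.955, 4.0, coarse_sizing)
        finer = MeshSizing(h_iso=0.5, h_tubing_surface=0.4,
                           h_impeller_surface=0.35, h_strut_surface=0.35,
                           bl_layers_central=3, bl_layers_peripheral=3)
        m2 = apply_boundary_layer(m, finer)
        assert m2.n_nodes > m.n_nodes

    def test_external_mesh_rejected(self, tiny_pipe):
        bare = Mesh(tiny_pipe.nodes, tiny_pipe.tets,
                    tiny_pipe.boundary_faces, tiny_pipe.face_tags)
        with pytest.raises(MeshError, match="provenance"):
            apply_boundary_layer(bare, MeshSizing())


class TestQualityMetrics:
    def test_regular_tetrahedron(self):
        a = 1.0
        nodes = np.array([[0, 0, 0], [a, 0, 0], [a / 2, a * np.sqrt(3) / 2, 0],
                          [a / 2, a * np.sqrt(3) / 6, a * np.sqrt(2.0 / 3)]])
        tets = np.array([[0, 1, 2, 3]])
        faces = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])
        m = Mesh(nodes, tets, faces, np.array(["w"] * 4))
        q = mesh_quality(m)
        assert q["mean_aspect_ratio"] == pytest.approx(1.0, abs=1e-9)
        assert q["min_dihedral_deg"] == pytest.approx(70.5288, abs=1e-3)
        assert q["mean_shape"] == pytest.approx(1.0, abs=1e-9)

    def test_sliver_unbounded_aspect(self):
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0],
                          [0.5, 0.5, 1e-4]])
        tets = np.array([[0, 1, 2, 3]])
        faces = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])
        m = Mesh(nodes, tets, faces, np.array(["w"] * 4))
        assert mesh_quality(m)["mean_aspect_ratio"] > 100.0

    def test_empty_mesh_errors(self):
        with pytest.raises(MeshError):
            mesh_quality(Mesh(np.zeros((0, 3)), np.zeros((0, 4), dtype=int),
                              np.zeros((0, 3), dtype=int), np.empty(0)))

    def test_inverted_tet_detected(self, tiny_pipe):
        bad = Mesh(tiny_pipe.nodes, tiny_pipe.tets[:, [0, 2, 1, 3]],
                   tiny_pipe.boundary_faces, tiny_pipe.face_tags)
        with pytest.raises(MeshError, match="non-positive"):
            bad.validate()
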