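"""Mesh data model, I/O round-trips, decimation, neighborhoods, edges."""
import numpy as np
import pytest
import trimesh

from osteomap import (RigidTransform, TriangleMesh, apply_transform, decimate,
                      mesh_edges, read_mesh, read_vertex_colors,
                      read_vertex_scalars, vertex_neighborhood, write_mesh)
from osteomap.errors import MeshInvariantError, MeshParseError

from conftest import random_rigid


class TestInvariants:
    def test_rejects_out_of_range_face_index(self):
        with pytest.raises(MeshInvariantError):
            TriangleMesh(np.zeros((3, 3)), np.array([[0, 1, 3]]))

    def test_rejects_degenerate_face(self):
        with pytest.raises(MeshInvariantError):
            TriangleMesh(np.eye(3), np.array([[0, 1, 1]]))

    def test_rejects_nonfinite_coordinates(self):
        v = np.eye(3)
        v[0, 0] = np.nan
        with pytest.raises(MeshInvariantError):
            TriangleMesh(v, np.array([[0, 1, 2]]))


class TestIO:
    @pytest.mark.parametrize("fmt", ["ply", "obj", "stl"])
    def test_roundtrip_preserves_geometry(self, tetrahedron, fmt, tmp_path):
        path = tmp_path / f"tet.{fmt}"
        write_mesh(tetrahedron, path, fmt)
        back = read_mesh(path, fmt)
        assert back.n_vertices == 4
        if fmt == "stl":
            # STL stores no connectivity; compare as point sets
            a = np.sort(tetrahedron.vertices.round(9), axis=0)
            b = np.sort(back.vertices.round(9), axis=0)
            np.testing.assert_allclose(a, b, atol=1e-6)
        else:
            np.testing.assert_allclose(back.vertices, tetrahedron.vertices,
                                       atol=1e-6)
            np.testing.assert_array_equal(back.faces, tetrahedron.faces)

    def test_roundtrip_precision_at_anatomical_scale(self, sphere, tmp_path):
        mesh = TriangleMesh(sphere.vertices + 100.0, sphere.faces)
        path = tmp_path / "far.ply"
        write_mesh(mesh, path)
        back = read_mesh(path)
        assert np.abs(back.vertices - mesh.vertices).max() < 1e-6

    def test_stl_welds_duplicated_corners(self, tetrahedron, tmp_path):
        path = tmp_path / "tet.stl"
        write_mesh(tetrahedron, path, "stl")
        # brute-force duplicate scan of the raw facet records
        raw = [ln.split()[1:] for ln in path.read_text().splitlines()
               if ln.strip().startswith("vertex")]
        assert len(raw) == 12  # 4 faces x 3 corners
        uniq = {tuple(map(float, r)) for r in raw}
        assert len(uniq) == 4
        assert read_mesh(path).n_vertices == 4

    def test_obj_zero_index_is_parse_error(self, tmp_path):
        p = tmp_path / "bad.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 0 1 2\n")
        with pytest.raises(MeshParseError, match="1-based"):
            read_mesh(p)

    def test_empty_mesh_is_error(self, tmp_path):
        p = tmp_path / "empty.obj"
        p.write_text("# nothing\n")
        with pytest.raises(MeshParseError):
            read_mesh(p)

    def test_scalar_and_color_channels(self, tetrahedron, tmp_path):
        path = tmp_path / "q.ply"
        scal = np.array([0.0, 0.5, 1.0, 2.0])
        cols = np.array([[255, 0, 0]] * 4)
        write_mesh(tetrahedron, path, per_vertex_scalars=scal,
                   per_vertex_colors=cols)
        assert "property float quality" in path.read_text()
        np.testing.assert_allclose(read_vertex_scalars(path), scal, atol=1e-6)
        np.testing.assert_array_equal(read_vertex_colors(path), cols)

    def test_scalar_length_mismatch_is_error(self, tetrahedron, tmp_path):
        with pytest.raises(ValueError):
            write_mesh(tetrahedron, tmp_path / "x.ply",
                       per_vertex_scalars=np.zeros(3))

    def test_colors_out_of_range_is_error(self, tetrahedron, tmp_path):
        with pytest.raises(ValueError, match=r"\[0, 255\]"):
            write_mesh(tetrahedron, tmp_path / "x.ply",
                       per_vertex_colors=np.full((4, 3), 300))

    def test_binary_ply_and_stl_read(self, small_sphere, tmp_path):
        tm = small_sphere.to_trimesh()
        for name, ft in (("b.ply", "ply"), ("b.stl", "stl")):
            path = tmp_path / name
            path.write_bytes(trimesh.exchange.export.export_mesh(
                tm, file_obj=None, file_type=ft))
            back = read_mesh(path)
            assert back.n_vertices == small_sphere.n_vertices


class TestDecimate:
    def test_exact_target_count(self, sphere):
        out = decimate(sphere, 653)
        assert out.n_vertices == 653
        assert out.to_trimesh().is_watertight

    def test_identity_when_target_equals_n(self, tetrahedron):
        out = decimate(tetrahedron, 4)
        np.testing.assert_array_equal(out.vertices, tetrahedron.vertices)

    def test_target_above_n_is_error(self, tetrahedron):
        with pytest.raises(ValueError):
            decimate(tetrahedron, 10)

    def test_sphere_radial_deviation_below_1pct(self, sphere):
        out = decimate(sphere, 653)
        radii = np.linalg.norm(out.vertices, axis=1)
        assert np.abs(radii - 10.0).mean() < 0.1  # 1% of radius


class TestNeighborhoodAndEdges:
    def test_tetrahedron_diameter_ball(self, tetrahedron):
        assert set(vertex_neighborhood(tetrahedron, 0, 2.0)) == {0, 1, 2, 3}

    def test_small_radius_gives_singleton(self, tetrahedron):
        assert list(vertex_neighborhood(tetrahedron, 0, 1e-3)) == [0]

    def test_matches_bruteforce_scan(self, small_sphere):
        rng = np.random.default_rng(3)
        for j in rng.choice(small_sphere.n_vertices, 10, replace=False):
            for r in (0.5, 2.0, 5.0):
                got = set(vertex_neighborhood(small_sphere, int(j), r))
                d = np.linalg.norm(small_sphere.vertices
                                   - small_sphere.vertices[j], axis=1)
                assert got == set(np.flatnonzero(d <= r))

    def test_geodesic_subset_of_euclidean(self, small_sphere):
        r = 4.0
        geo = set(vertex_neighborhood(small_sphere, 0, r, metric="geodesic"))
        euc = set(vertex_neighborhood(small_sphere, 0, r))
        assert geo <= euc and 0 in geo

    def test_tetrahedron_is_k4(self, tetrahedron):
        assert len(mesh_edges(tetrahedron)) == 6

    def test_closed_genus0_edge_count(self, sphere):
        assert len(mesh_edges(sphere)) == 3 * sphere.n_vertices - 6

    def test_two_face_strip_has_5_edges(self):
        m = TriangleMesh(np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0],
                                   [1, 1, 0]]),
                         np.array([[0, 1, 2], [1, 3, 2]]))
        assert len(mesh_edges(m)) == 5


class TestApplyTransform:
    def test_identity(self, tetrahedron):
        out = apply_transform(tetrahedron, RigidTransform.identity())
        np.testing.assert_array_equal(out.vertices, tetrahedron.vertices)

    def test_quarter_turn_about_z(self):
        T = RigidTransform(np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]]),
                           np.zeros(3))
        np.testing.assert_allclose(T.apply(np.array([1.0, 0, 0])),
                                   [0, 1, 0], atol=1e-15)

    def test_transform_then_inverse_is_identity(self, sphere):
        rng = np.random.default_rng(0)
        T = random_rigid(rng, max_angle=3.0)
        back = apply_transform(apply_transform(sphere, T), T.inverse())
        assert np.abs(back.vertices - sphere.vertices).max() < 1e-9

    def test_rigidity_preserves_pairwise_distances(self, small_sphere):
        rng = np.random.default_rng(1)
        T = random_rigid(rng, max_angle=3.0)
        out = apply_transform(small_sphere, T)
        idx = rng.choice(small_sphere.n_vertices, 40, replace=False)
        d0 = np.linalg.norm(small_sphere.vertices[idx][:, None]
                            - small_sphere.vertices[idx][None], axis=-1)
        d1 = np.linalg.norm(out.vertices[idx][:, None]
                            - out.vertices[idx][None], axis=-1)
        assert np.abs(d0 - d1).max() < 1e-9

    def test_non_orthonormal_rotation_rejected(self):
        with pytest.raises(Exception):
            RigidTransform(np.eye(3) * 1.1, np.zeros(3))
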