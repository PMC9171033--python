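"""Correlation matching: ICP pre-alignment, scoring, vertex matching, chains."""
import numpy as np
import pytest

from osteomap import (CorrespondenceParams, GrowthScenario, Neighborhood,
                      RigidTransform, TriangleMesh, apply_transform,
                      build_correspondence, compose_correspondence,
                      global_align, grow_series, identity_correspondence,
                      match_vertex, neighborhood_correlation)
from osteomap.correspondence import _PairContext
from osteomap.errors import (ChainMismatchError, DegenerateGeometryError,
                             NoCandidateError, UndefinedScoreError)

from conftest import random_rigid


def brute_force_match(source, target, j, r, pre_align, refine_iters=5,
                      score_tol=5e-3, target_radius_factor=1.3):
    """Independent exhaustive oracle: evaluate every target vertex as a
    candidate with an independently coded refine + Pearson correlation."""
    from scipy.spatial import cKDTree

    src_tree = cKDTree(source.vertices)
    tgt_tree = cKDTree(target.vertices)
    P = source.vertices[sorted(src_tree.query_ball_point(source.vertices[j], r))]
    p0 = pre_align.apply(source.vertices[j])
    results = []
    for c in range(target.n_vertices):
        Q = target.vertices[sorted(tgt_tree.query_ball_point(
            target.vertices[c], r * target_radius_factor))]
        R, t = pre_align.rotation, pre_align.translation + target.vertices[c] - p0
        prev = None
        for _ in range(refine_iters):
            X = P @ R.T + t
            idx = np.argmin(((X[:, None] - Q[None]) ** 2).sum(-1), axis=1)
            if prev is not None and np.array_equal(idx, prev):
                break
            prev = idx
            Y = Q[idx]
            cp, cq = P.mean(0), Y.mean(0)
            U, S, Vt = np.linalg.svd((P - cp).T @ (Y - cq))
            D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T)) or 1.0])
            R = Vt.T @ D @ U.T
            t = cq - R @ cp
        X = P @ R.T + t
        idx = np.argmin(((X[:, None] - Q[None]) ** 2).sum(-1), axis=1)
        Y = Q[idx]
        x = (X - X.mean(0)).ravel()
        y = (Y - Y.mean(0)).ravel()
        vx, vy = (x * x).mean(), (y * y).mean()
        if vx == 0 or vy == 0:
            continue
        score = min(1.0, max(-1.0, (x * y).mean() / np.sqrt(vx * vy)))
        if abs(score - 1.0) < 1e-13:
            score = 1.0
        dist = np.linalg.norm(target.vertices[c] - p0)
        results.append((score, dist, c))
    top = max(s for s, _, _ in results)
    tied = [(d, c) for s, d, c in results if s >= top - score_tol]
    return min(tied)[1]


def bumpy_mesh(seed, n_target=None, radius=5.0):
    """Small closed mesh with smooth random radial features."""
    import trimesh

    rng = np.random.default_rng(seed)
    m = trimesh.creation.icosphere(subdivisions=1, radius=radius)
    v = np.asarray(m.vertices)
    dirs = v / np.linalg.norm(v, axis=1, keepdims=True)
    bump = 1.0 + 0.15 * np.sin(dirs @ rng.normal(0, 1.5, 3)) \
        + 0.1 * np.cos(dirs @ rng.normal(0, 2.0, 3))
    return TriangleMesh(v * bump[:, None], np.asarray(m.faces))


def smooth_deform(mesh, seed, scale=0.2):
    """Smooth random deformation bounded by ``scale`` x mean edge length."""
    rng = np.random.default_rng(seed)
    amp = scale * mesh.mean_edge_length()
    v = mesh.vertices
    disp = np.stack([np.sin(v @ rng.normal(0, 0.2, 3) + rng.uniform(0, 6))
                     for _ in range(3)], axis=1)
    return TriangleMesh(v + amp * disp / np.abs(disp).max(),
                        mesh.faces.copy())


class TestGlobalAlign:
    def test_recovers_known_rigid_motion(self, small_sphere):
        mesh = bumpy_mesh(0, radius=10.0)
        rng = np.random.default_rng(1)
        T = random_rigid(rng, max_angle=0.3)
        target = apply_transform(mesh, T)
        res = global_align(mesh, target)
        assert res.rms < 1e-6
        np.testing.assert_allclose(res.transform.rotation, T.rotation,
                                   atol=1e-6)
        np.testing.assert_allclose(res.transform.translation, T.translation,
                                   atol=1e-5)

    def test_identical_meshes_identity(self, small_sphere):
        res = global_align(small_sphere, small_sphere)
        np.testing.assert_allclose(res.transform.rotation, np.eye(3),
                                   atol=1e-9)
        assert res.rms < 1e-9

    def test_scaled_target_matches_direct_kabsch_rms(self):
        from osteomap.rigid import kabsch

        mesh = bumpy_mesh(2)
        target = TriangleMesh(mesh.vertices * 1.02, mesh.faces.copy())
        res = global_align(mesh, target)
        T = kabsch(mesh.vertices, target.vertices)
        d = np.linalg.norm(T.apply(mesh.vertices) - target.vertices, axis=1)
        rms_known = np.sqrt((d ** 2).mean())
        assert res.rms > 0
        assert res.rms <= rms_known + 1e-9

    def test_collinear_vertices_degenerate(self):
        line = TriangleMesh(np.c_[np.arange(4.0), np.zeros(4), np.zeros(4)]
                            + 1e-12, np.array([[0, 1, 2], [1, 2, 3]]))
        with pytest.raises(DegenerateGeometryError):
            global_align(line, line)


class TestNeighborhoodCorrelation:
    def test_exact_transform_scores_one(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 2, (12, 3))
        T = random_rigid(rng, max_angle=1.0)
        q1 = Neighborhood(0, pts, 5.0)
        q2 = Neighborhood(0, T.apply(pts), 5.0)
        assert neighborhood_correlation(q1, q2, T) == 1.0

    def test_inverted_neighborhood_anticorrelates(self):
        # Point inversion of the target cannot reach exactly -1 under
        # nearest-neighbor pairing (the largest-norm point always pairs
        # elsewhere), but the score must drop far below the aligned case.
        rng = np.random.default_rng(4)
        pts = rng.normal(0, 2, (10, 3))
        q1 = Neighborhood(0, pts, 8.0)
        aligned = neighborhood_correlation(
            q1, Neighborhood(0, pts.copy(), 8.0), RigidTransform.identity())
        inverted = neighborhood_correlation(
            q1, Neighborhood(0, 2 * pts.mean(0) - pts, 8.0),
            RigidTransform.identity())
        assert aligned == 1.0
        assert -1.0 <= inverted < aligned - 0.1

    def test_matches_handrolled_pearson(self):
        rng = np.random.default_rng(5)
        src = rng.normal(0, 3, (10, 3))
        tgt = rng.normal(0, 3, (10, 3))
        T = RigidTransform.identity()
        got = neighborhood_correlation(Neighborhood(0, src, 9.0),
                                       Neighborhood(0, tgt, 9.0), T)
        idx = np.argmin(((src[:, None] - tgt[None]) ** 2).sum(-1), axis=1)
        x = (src - src.mean(0)).ravel()
        Y = tgt[idx]
        y = (Y - Y.mean(0)).ravel()
        want = np.corrcoef(x, y)[0, 1]
        assert got == pytest.approx(want, abs=1e-12)

    def test_zero_variance_is_error(self):
        pts = np.zeros((5, 3))
        with pytest.raises(UndefinedScoreError):
            neighborhood_correlation(Neighborhood(0, pts, 1.0),
                                     Neighborhood(0, pts, 1.0),
                                     RigidTransform.identity())

    def test_scores_bounded(self):
        rng = np.random.default_rng(6)
        for seed in range(5):
            src = rng.normal(0, 2, (8, 3))
            tgt = rng.normal(0, 2, (11, 3))
            s = neighborhood_correlation(Neighborhood(0, src, 9.0),
                                         Neighborhood(0, tgt, 9.0),
                                         RigidTransform.identity())
            assert -1.0 <= s <= 1.0


class TestMatchVertex:
    def test_identical_meshes_identity_match(self):
        mesh = bumpy_mesh(7)
        mel = mesh.mean_edge_length()
        for j in (0, 5, 17):
            m = match_vertex(mesh, mesh, j, 5 * mel, 3 * mel,
                             RigidTransform.identity())
            assert m.target_index == j
            assert m.score == 1.0

    def test_scaled_sphere_same_direction(self):
        mesh = bumpy_mesh(8)
        target = TriangleMesh(mesh.vertices * 1.05, mesh.faces.copy())
        mel = mesh.mean_edge_length()
        pre = global_align(mesh, target).transform
        hits = 0
        for j in range(mesh.n_vertices):
            m = match_vertex(mesh, target, j, 5 * mel, 3 * mel, pre)
            hits += (m.target_index == j)
        assert hits >= 0.9 * mesh.n_vertices

    def test_no_candidate_error(self):
        mesh = bumpy_mesh(9)
        far = TriangleMesh(mesh.vertices + 1000.0, mesh.faces.copy())
        with pytest.raises(NoCandidateError):
            match_vertex(mesh, far, 0, 5.0, 0.5, RigidTransform.identity())

    def test_equals_bruteforce_oracle_on_deformed_mesh(self):
        mesh = bumpy_mesh(10)
        target = smooth_deform(mesh, 11)
        mel = mesh.mean_edge_length()
        pre = global_align(mesh, target).transform
        rng = np.random.default_rng(12)
        for j in rng.choice(mesh.n_vertices, 8, replace=False):
            got = match_vertex(mesh, target, int(j), 5 * mel, np.inf, pre)
            want = brute_force_match(mesh, target, int(j), 5 * mel, pre)
            assert got.target_index == want

    def test_local_transforms_are_rotations(self):
        mesh = bumpy_mesh(13)
        target = smooth_deform(mesh, 14)
        pre = global_align(mesh, target).transform
        mel = mesh.mean_edge_length()
        m = match_vertex(mesh, target, 3, 5 * mel, 3 * mel, pre)
        R = m.transform.rotation
        assert np.abs(R.T @ R - np.eye(3)).max() < 1e-9
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)


class TestBuildAndCompose:
    def test_identical_meshes_identity_map(self):
        mesh = bumpy_mesh(15)
        m = build_correspondence(mesh, mesh)
        assert (m.target_index == np.arange(mesh.n_vertices)).all()
        assert (m.score == 1.0).all()

    def test_equivariance_under_target_rigid_motion(self):
        mesh = bumpy_mesh(16)
        target = smooth_deform(mesh, 17)
        rng = np.random.default_rng(18)
        T = random_rigid(rng, max_angle=0.2)
        m0 = build_correspondence(mesh, target)
        m1 = build_correspondence(mesh, apply_transform(target, T))
        assert (m0.target_index == m1.target_index).all()
        assert np.abs(m0.score - m1.score).max() < 1e-9

    def test_synthetic_pair_ground_truth_recovery(self, small_template):
        sc = GrowthScenario.uniform(rate=2.0, n_instances=4, noise_sigma=0.0)
        data = grow_series(small_template, sc)
        from osteomap import mesh_edges
        edges = mesh_edges(small_template.mesh)
        adj = {}
        for a, b in edges:
            adj.setdefault(int(a), set()).add(int(b))
            adj.setdefault(int(b), set()).add(int(a))
        m = build_correspondence(data.noiseless[0], data.noiseless[1])
        ok = sum(int(t == j or t in adj[j])
                 for j, t in enumerate(m.target_index))
        assert ok >= 0.95 * m.n_source

    def test_symmetric_pair_inverse_relation(self):
        mesh = bumpy_mesh(19)
        target = TriangleMesh(mesh.vertices * 1.01, mesh.faces.copy())
        fwd = build_correspondence(mesh, target)
        bwd = build_correspondence(target, mesh)
        inverse_ok = sum(int(bwd.target_index[fwd.target_index[j]] == j)
                         for j in range(mesh.n_vertices))
        assert inverse_ok >= 0.95 * mesh.n_vertices

    def test_compose_identity_chain(self):
        mesh = bumpy_mesh(20)
        maps = [identity_correspondence(mesh) for _ in range(3)]
        comp = compose_correspondence(maps)
        assert (comp.target_index == np.arange(mesh.n_vertices)).all()

    def test_compose_mutual_inverses(self):
        mesh = bumpy_mesh(21)
        target = TriangleMesh(mesh.vertices * 1.01, mesh.faces.copy())
        fwd = build_correspondence(mesh, target)
        bwd = build_correspondence(target, mesh)
        comp = compose_correspondence([fwd, bwd])
        frac = (comp.target_index == np.arange(mesh.n_vertices)).mean()
        assert frac >= 0.95

    def test_compose_chain_mismatch_is_error(self, tetrahedron, small_sphere):
        m1 = identity_correspondence(tetrahedron)
        m2 = identity_correspondence(small_sphere)
        with pytest.raises(ChainMismatchError):
            compose_correspondence([m1, m2])

    def test_synthetic_series_composed_map(self, small_template):
        sc = GrowthScenario.uniform(rate=1.5, n_instances=4, noise_sigma=0.0)
        data = grow_series(small_template, sc)
        maps = [build_correspondence(data.noiseless[i], data.noiseless[i + 1])
                for i in range(3)]
        comp = compose_correspondence(maps)
        frac = (comp.target_index
                == np.arange(small_template.mesh.n_vertices)).mean()
        assert frac >= 0.90
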