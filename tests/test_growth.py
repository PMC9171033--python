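"""Normalized changes, spline rates, vertex aggregation, directional split."""
import numpy as np
import pytest

from osteomap import (GrowthScenario, MeshSeries, TriangleMesh,
                      directional_decompose, edge_length_changes, edge_rates,
                      fit_growth_curve, grow_series, identity_correspondence,
                      mesh_edges, rate_at_instance, vertex_rates)
from osteomap.synthetic import TemplateParams, make_template_mandible


def _series_of_scaled(mesh, factors, times=None):
    meshes = [mesh]
    C = mesh.vertices.mean(0)
    for f in factors:
        prev = meshes[-1]
        meshes.append(TriangleMesh(C + f * (prev.vertices - C),
                                   mesh.faces.copy()))
    times = times if times is not None else np.arange(1, len(meshes) + 1)
    return MeshSeries(meshes, times)


class TestEdgeChanges:
    def test_five_percent_growth_arithmetic(self, tetrahedron):
        series = _series_of_scaled(tetrahedron, [1.05] * 3)
        maps = [identity_correspondence(m) for m in series.meshes[:-1]]
        table = edge_length_changes(series, maps)
        np.testing.assert_allclose(table.changes, 5.0, atol=1e-9)

    def test_identical_meshes_zero_change(self, tetrahedron):
        series = _series_of_scaled(tetrahedron, [1.0] * 3)
        maps = [identity_correspondence(m) for m in series.meshes[:-1]]
        assert np.abs(edge_length_changes(series, maps).changes).max() == 0.0

    def test_change_assigned_to_interval_end(self, tetrahedron):
        # growth only in the last interval shows up in the last column
        series = _series_of_scaled(tetrahedron, [1.0, 1.0, 1.02])
        maps = [identity_correspondence(m) for m in series.meshes[:-1]]
        table = edge_length_changes(series, maps)
        assert np.abs(table.changes[:, :2]).max() == 0.0
        np.testing.assert_allclose(table.changes[:, 2], 2.0, atol=1e-9)


class TestSpline:
    def test_constant_change_gives_constant_rate(self):
        times = np.arange(1, 13, dtype=float)
        curve = fit_growth_curve(times, np.full(11, 1.7))
        for t in times:
            assert abs(rate_at_instance(curve, t) - 1.7) < 1e-9

    def test_cubic_data_interpolated_exactly_at_zero_smoothing(self):
        times = np.arange(1, 9, dtype=float)
        cum = 0.05 * times ** 3 - 0.3 * times ** 2 + times - 0.75
        changes = np.diff(cum)
        curve = fit_growth_curve(times, changes, smoothing=0.0)
        np.testing.assert_allclose(curve.cumulative(times), cum - cum[0],
                                   atol=1e-9)
        # derivative of the cubic: 0.15 t^2 - 0.6 t + 1
        np.testing.assert_allclose(curve.rate(times),
                                   0.15 * times ** 2 - 0.6 * times + 1,
                                   atol=1e-8)

    def test_quadratic_rate_is_2t(self):
        times = np.arange(0, 6, dtype=float)
        changes = np.diff(times ** 2)
        curve = fit_growth_curve(times, changes, smoothing=0.0)
        np.testing.assert_allclose(curve.rate(times), 2 * times, atol=1e-8)

    def test_noisy_linear_slope_recovery(self):
        rng = np.random.default_rng(5)
        times = np.arange(1, 13, dtype=float)
        slope = 2.0
        cum = slope * (times - 1) + rng.normal(0, 0.05, len(times))
        cum -= cum[0]
        curve = fit_growth_curve(times, np.diff(cum), smoothing=len(times) * 0.05 ** 2)
        # least-squares slope estimate: sd(slope) ~ sigma/sqrt(n var(t))
        mean_rate = np.mean(curve.rate(times))
        assert abs(mean_rate - slope) < 3 * 0.05 / np.sqrt(len(times)) * 5

    def test_too_few_instances_is_error(self):
        with pytest.raises(ValueError):
            fit_growth_curve(np.array([1.0, 2, 3]), np.array([1.0, 1]))

    def test_extrapolation_is_error(self):
        curve = fit_growth_curve(np.arange(1.0, 6), np.ones(4))
        with pytest.raises(ValueError):
            curve.rate(7.0)


class TestVertexRates:
    def test_mean_of_incident_edges(self):
        edges = np.array([[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]])
        er = np.array([[1.0], [2.0], [3.0], [5.0], [5.0], [5.0]])
        vr = vertex_rates(er, edges, 4)
        assert vr[0, 0] == pytest.approx(2.0)

    def test_single_incident_edge(self):
        edges = np.array([[0, 1], [1, 2]])
        er = np.array([[4.0], [8.0]])
        vr = vertex_rates(er, edges, 3)
        assert vr[0, 0] == 4.0 and vr[2, 0] == 8.0

    def test_isolated_vertex_is_error(self):
        with pytest.raises(ValueError, match="isolated"):
            vertex_rates(np.ones((1, 2)), np.array([[0, 1]]), 3)


class TestDirectionalDecompose:
    axes = np.array([[0.0, 1, 0], [0, 0, 1], [1.0, 0, 0]])  # ap, si, ml

    def test_axis_aligned_edge(self):
        m = TriangleMesh(np.array([[0.0, 0, 0], [0, 3, 0], [0, 0, 3]]),
                         np.array([[0, 1, 2]]))
        comps = directional_decompose(np.array([[1.0]]), np.array([[0, 1]]),
                                      m, self.axes)
        assert comps["ap"][0, 0] == pytest.approx(1.0)
        assert comps["si"][0, 0] == pytest.approx(0.0)

    def test_diagonal_edge_splits_equally(self):
        m = TriangleMesh(np.array([[0.0, 0, 0], [1, 1, 1], [0, 0, 3]]),
                         np.array([[0, 1, 2]]))
        comps = directional_decompose(np.array([[3.0]]), np.array([[0, 1]]),
                                      m, self.axes)
        for k in ("ap", "si", "ml"):
            assert comps[k][0, 0] == pytest.approx(1.0)

    def test_components_conserve_total(self, small_sphere):
        rng = np.random.default_rng(2)
        edges = mesh_edges(small_sphere)
        er = rng.normal(0, 1, (len(edges), 4))
        comps = directional_decompose(er, edges, small_sphere, self.axes)
        total = comps["ap"] + comps["si"] + comps["ml"]
        assert np.abs(total - er).max() < 1e-12


class TestSyntheticTruth:
    def test_zero_rates_give_zero_field(self, small_template):
        sc = GrowthScenario.uniform(rate=0.0, n_instances=5)
        data = grow_series(small_template, sc)
        assert np.abs(data.truth.total).max() < 1e-9

    def test_uniform_scaling_rates_equal_everywhere(self, small_template):
        sc = GrowthScenario.uniform(rate=2.0, n_instances=6)
        data = grow_series(small_template, sc)
        np.testing.assert_allclose(data.truth.total, 2.0, atol=1e-9)

    def test_rates_rigid_motion_invariant(self, small_template):
        from conftest import random_rigid

        from osteomap import apply_transform, compute_growth_field

        sc = GrowthScenario.uniform(rate=1.5, n_instances=5)
        data = grow_series(small_template, sc)
        rng = np.random.default_rng(9)
        T = random_rigid(rng)
        moved = MeshSeries([apply_transform(m, T)
                            for m in data.noiseless.meshes],
                           data.noiseless.times)
        f2 = compute_growth_field(moved, data.maps)
        assert np.abs(f2.total - data.truth.total).max() < 1e-9

    def test_decelerating_growth_monotone_rates(self, small_template):
        sc = GrowthScenario.uniform(rate=2.0, n_instances=8, noise_sigma=0.0)
        halving = 2.0 * 0.5 ** np.arange(7)
        sc = GrowthScenario(region_rates=sc.region_rates, n_instances=8,
                            noise_sigma=0.0, temporal_profile=halving / 2.0)
        data = grow_series(small_template, sc)
        mid = data.truth.total[:, 2:-2]  # splines can wiggle at the ends
        assert (np.diff(mid, axis=1) < 1e-6).all()
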