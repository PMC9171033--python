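"""Synthetic growing-mandible series with known ground truth.

The template is a closed, watertight horseshoe arch (corpus) with two
posterior vertical rami bearing bulged condyle knobs, built by sweeping a
circular cross-section along a spline centerline.  Smooth low-order radial
bumps are superimposed so that local surface neighborhoods carry
distinguishing morphological features, as real bone does — a perfectly
smooth tube would be locally rotation-symmetric and correspondence by
correlation would be ill-posed.

Growth displaces each vertex away from the template centroid by a smooth
per-vertex rate field interpolated from per-region target rates, scaled per
interval by a decaying temporal profile; measurement noise is Gaussian along
vertex normals (surface-reconstruction-like, no tangential drift).  Vertex
identity is preserved, so the ground-truth correspondence is the identity
map and ground-truth rates follow in closed form from the noiseless
coordinates.

Defaults emulate growing minipig mandibles monitored monthly over a year:
12 instances, 653 vertices, rates of roughly 0.3-2 %/month decreasing from
condyle to corpus and decelerating over time, and 0.2 mm measurement noise.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, Optional

import numpy as np
from scipy.interpolate import CubicSpline

from .anatomy import LandmarkSet, RegionLabels
from .correspondence import identity_correspondence
from .growth import GrowthField, compute_growth_field
from .mesh import MeshSeries, TriangleMesh, decimate, mesh_edges


@dataclass
class TemplateParams:
    """Geometry of the schematic mandible (mm)."""

    n_vertices: int = 653
    base_radius: float = 4.5
    condyle_bulge: float = 2.5
    bump_amplitude: float = 0.12   # relative radius modulation (features)
    arch_width: float = 24.0       # hemi-arch lateral extent
    arch_length: float = 20.0      # chin protrusion
    ramus_height: float = 26.0


@dataclass
class GrowthScenario:
    """Study conditions for a synthetic series.

    ``region_rates`` are base %/month rates per region (scaled by the
    temporal profile); ``noise_sigma`` is the measurement noise (mm) along
    vertex normals; the default profile decays from 1.0 to 0.3 over the
    intervals, emulating decelerating juvenile growth.
    """

    region_rates: Dict[str, float] = dc_field(default_factory=lambda: {
        "condyle": 1.9, "posterior_ramus": 1.5, "anterior_ramus": 1.0,
        "posterior_corpus": 0.4, "middle_corpus": 0.4, "anterior_corpus": 0.4,
    })
    n_instances: int = 12
    noise_sigma: float = 0.2
    temporal_profile: Optional[np.ndarray] = None
    smooth_iters: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_instances < 2:
            raise ValueError("need at least 2 instances")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        for k, v in self.region_rates.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite rate for region {k!r}")
        if self.temporal_profile is None:
            K = self.n_instances
            self.temporal_profile = np.geomspace(1.0, 0.3, K - 1) \
                if K > 2 else np.ones(K - 1)
        self.temporal_profile = np.asarray(self.temporal_profile, float)
        if len(self.temporal_profile) != self.n_instances - 1:
            raise ValueError("temporal profile needs one value per interval")

    @classmethod
    def uniform(cls, rate: float = 2.0, n_instances: int = 12,
                noise_sigma: float = 0.0, seed: int = 0) -> "GrowthScenario":
        """Uniform isotropic growth: every edge grows by exactly ``rate`` %/interval."""
        rates = {r: rate for r in ("condyle", "posterior_ramus", "anterior_ramus",
                                   "posterior_corpus", "middle_corpus",
                                   "anterior_corpus")}
        return cls(region_rates=rates, n_instances=n_instances,
                   noise_sigma=noise_sigma,
                   temporal_profile=np.ones(n_instances - 1), seed=seed)


@dataclass
class MandibleTemplate:
    mesh: TriangleMesh
    landmarks: LandmarkSet
    labels: RegionLabels


@dataclass
class SyntheticSeries:
    """A generated series with its full ground truth."""

    template: MandibleTemplate
    scenario: GrowthScenario
    series: MeshSeries                 # noisy (measured) meshes
    noiseless: MeshSeries
    maps: list                         # ground-truth identity correspondences
    truth: GrowthField                 # rates from the noiseless coordinates


# -- template construction --------------------------------------------------

def _centerline(params: TemplateParams):
    w, l, h = params.arch_width, params.arch_length, params.ramus_height
    left = np.array([
        [w, -28.0, h],          # condyle top
        [w, -28.0, h * 0.6],
        [w, -27.0, 6.0],        # upper ramus
        [w - 1.0, -24.0, 0.0],  # gonial angle
        [w - 4.0, -12.0, 0.0],
        [w - 9.0, 2.0, 1.0],
        [w - 16.0, l * 0.7, 1.5],
        [0.0, l, 2.0],          # chin midline
    ])
    right = left[::-1].copy()
    right[:, 0] *= -1
    pts = np.vstack([left, right[1:]])
    chord = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
    s = chord / chord[-1]
    return CubicSpline(s, pts, axis=0)


def _parallel_frames(tangents: np.ndarray):
    """Rotation-minimizing normal frames along the centerline."""
    e1 = np.empty_like(tangents)
    ref = np.array([0.0, 0.0, 1.0])
    t0 = tangents[0]
    v = ref - (ref @ t0) * t0
    if np.linalg.norm(v) < 1e-6:
        v = np.array([0.0, 1.0, 0.0]) - (np.array([0.0, 1.0, 0.0]) @ t0) * t0
    e1[0] = v / np.linalg.norm(v)
    for i in range(1, len(tangents)):
        v = e1[i - 1] - (e1[i - 1] @ tangents[i]) * tangents[i]
        e1[i] = v / np.linalg.norm(v)
    e2 = np.cross(tangents, e1)
    return e1, e2


def make_template_mandible(params: Optional[TemplateParams] = None,
                           seed: int = 0) -> MandibleTemplate:
    """Closed watertight mandible-like surface with landmarks and region labels.

    Deterministic per seed (the seed sets the phases of the feature bumps).
    """
    params = params or TemplateParams()
    if params.n_vertices < 100:
        raise ValueError("target vertex count must be >= 100")
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0, 2 * np.pi, size=4)

    n_grid = int(round(params.n_vertices * 1.3))
    nt = max(10, int(round(np.sqrt(n_grid / 5.0))))
    ns = max(8, n_grid // nt)
    curve = _centerline(params)
    s = np.linspace(0.0, 1.0, ns)
    centers = curve(s)
    tang = curve(s, 1)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    e1, e2 = _parallel_frames(tang)

    bulge = params.condyle_bulge
    radius = params.base_radius + bulge * (
        np.exp(-(s / 0.06) ** 2) + np.exp(-((1 - s) / 0.06) ** 2))
    theta = np.linspace(0, 2 * np.pi, nt, endpoint=False)

    A = params.bump_amplitude
    S, TH = np.meshgrid(s, theta, indexing="ij")
    mod = 1.0 + A * (np.sin(3 * TH + 7 * S + phases[0])
                     + 0.6 * np.cos(2 * TH - 11 * S + phases[1])
                     + 0.4 * np.sin(5 * TH + 3 * S + phases[2])) / 2.0
    rr = radius[:, None] * mod
    ring = (centers[:, None, :]
            + rr[:, :, None] * (np.cos(theta)[None, :, None] * e1[:, None, :]
                                + np.sin(theta)[None, :, None] * e2[:, None, :]))
    V = ring.reshape(-1, 3)
    cap0 = centers[0] - tang[0] * radius[0] * 0.9
    cap1 = centers[-1] + tang[-1] * radius[-1] * 0.9
    V = np.vstack([V, cap0, cap1])
    i0, i1 = len(V) - 2, len(V) - 1

    faces = []
    for i in range(ns - 1):
        for k in range(nt):
            a = i * nt + k
            b = i * nt + (k + 1) % nt
            c = (i + 1) * nt + k
            d = (i + 1) * nt + (k + 1) % nt
            faces.append([a, c, d])
            faces.append([a, d, b])
    for k in range(nt):
        faces.append([i0, k, (k + 1) % nt])
        faces.append([i1, (ns - 1) * nt + (k + 1) % nt, (ns - 1) * nt + k])
    mesh = TriangleMesh(V, np.asarray(faces, np.int64), "template")
    tm = mesh.to_trimesh()
    if tm.volume < 0:  # enforce outward winding
        mesh.faces = mesh.faces[:, [0, 2, 1]]
    mesh = decimate(mesh, params.n_vertices)
    mesh = _relax_tangentially(mesh, iters=15)
    mesh.instance_label = "template"

    labels = RegionLabels(_label_regions(mesh.vertices, params))
    landmarks = _extract_landmarks(mesh.vertices, labels)
    return MandibleTemplate(mesh, landmarks, labels)


def _relax_tangentially(mesh: TriangleMesh, iters: int = 15,
                        step: float = 0.5) -> TriangleMesh:
    """Equalize vertex spacing without changing the shape.

    Tangential Laplacian relaxation: each vertex moves toward the centroid of
    its neighbors, with the motion component along the vertex normal removed.
    Decimation can leave near-duplicate vertices (edges far shorter than the
    mean); reconstructed bone surfaces are sampled nearly uniformly, so the
    template is relaxed to match that character.
    """
    edges = mesh_edges(mesh)
    n = mesh.n_vertices
    deg = np.zeros(n)
    np.add.at(deg, edges[:, 0], 1)
    np.add.at(deg, edges[:, 1], 1)
    v = mesh.vertices.copy()
    for _ in range(iters):
        normals = TriangleMesh(v, mesh.faces).vertex_normals()
        acc = np.zeros_like(v)
        np.add.at(acc, edges[:, 0], v[edges[:, 1]])
        np.add.at(acc, edges[:, 1], v[edges[:, 0]])
        disp = acc / deg[:, None] - v
        disp -= np.einsum("ij,ij->i", disp, normals)[:, None] * normals
        v = v + step * disp
    return TriangleMesh(v, mesh.faces.copy(), mesh.instance_label)


def _label_regions(V: np.ndarray, params: TemplateParams) -> np.ndarray:
    x, y, z = V[:, 0], V[:, 1], V[:, 2]
    h = params.ramus_height
    labels = np.empty(len(V), object)
    condyle = z >= h - 8.0
    ramus = (~condyle) & (z > 4.0)
    post_ramus = ramus & (y <= -26.0)
    ant_ramus = ramus & (y > -26.0)
    corpus = ~(condyle | ramus)
    post_corpus = corpus & (y < -8.0)
    mid_corpus = corpus & (y >= -8.0) & (y < 10.0)
    ant_corpus = corpus & (y >= 10.0)
    labels[condyle] = "condyle"
    labels[post_ramus] = "posterior_ramus"
    labels[ant_ramus] = "anterior_ramus"
    labels[post_corpus] = "posterior_corpus"
    labels[mid_corpus] = "middle_corpus"
    labels[ant_corpus] = "anterior_corpus"
    return labels.astype(str)


def _extract_landmarks(V: np.ndarray, labels: RegionLabels) -> LandmarkSet:
    x, y, z = V[:, 0], V[:, 1], V[:, 2]
    lab = labels.labels
    out = {}
    mid = np.abs(x) <= 4.0
    out["GT"] = V[np.flatnonzero(mid)[np.argmax(y[mid])]]
    for side, sgn in (("L", 1.0), ("R", -1.0)):
        sx = sgn * x
        cond = np.flatnonzero((lab == "condyle") & (sx > 0))
        ram = np.flatnonzero((lab == "posterior_ramus") | (lab == "anterior_ramus"))
        ram = ram[sx[ram] > 0]
        side_all = np.flatnonzero(sx > 0)
        corp = np.flatnonzero((sx > 0) & (z <= 4.0))
        out[f"{side}_Cd-lat"] = V[cond[np.argmax(sx[cond])]]
        out[f"{side}_Cd-med"] = V[cond[np.argmin(sx[cond])]]
        out[f"{side}_Cr"] = V[ram[np.argmax(y[ram] + z[ram])]]
        out[f"{side}_Go"] = V[side_all[np.argmin(y[side_all] + z[side_all])]]
        for name, y0 in (("MF1", 12.0), ("MF2", 4.0), ("MF3", -4.0)):
            score = sx[corp] - 2.0 * np.abs(y[corp] - y0)
            out[f"{side}_{name}"] = V[corp[np.argmax(score)]]
        anchor = np.array([sgn * 4.0, 16.0, 0.0])
        out[f"{side}_GF"] = V[np.argmin(np.linalg.norm(V - anchor, axis=1))]
    return LandmarkSet(out)


# -- growth -----------------------------------------------------------------

def _smooth_vertex_field(values: np.ndarray, edges: np.ndarray,
                         iters: int) -> np.ndarray:
    n = len(values)
    deg = np.zeros(n)
    np.add.at(deg, edges[:, 0], 1)
    np.add.at(deg, edges[:, 1], 1)
    w = values.astype(float).copy()
    for _ in range(iters):
        acc = np.zeros(n)
        np.add.at(acc, edges[:, 0], w[edges[:, 1]])
        np.add.at(acc, edges[:, 1], w[edges[:, 0]])
        w = 0.5 * w + 0.5 * acc / np.maximum(deg, 1)
    return w


def vertex_rate_field(template: MandibleTemplate,
                      scenario: GrowthScenario) -> np.ndarray:
    """Smooth per-vertex base rate field interpolating the per-region rates."""
    w0 = np.array([scenario.region_rates[l] for l in template.labels.labels])
    edges = mesh_edges(template.mesh)
    return _smooth_vertex_field(w0, edges, scenario.smooth_iters)


def grow_series(template: MandibleTemplate,
                scenario: GrowthScenario) -> SyntheticSeries:
    """Generate the series, ground-truth maps and ground-truth rates.

    Instance i+1 scales each vertex away from the template centroid by
    1 + w(v) p_i / 100, where w is the smooth rate field and p the temporal
    profile; iid Gaussian noise of ``noise_sigma`` mm is then added along the
    vertex normals of each instance independently.
    """
    mesh = template.mesh
    rng = np.random.default_rng(scenario.seed)
    w = vertex_rate_field(template, scenario)
    C = mesh.vertices.mean(axis=0)
    K = scenario.n_instances
    edges = mesh_edges(mesh)

    clean = [mesh.vertices.copy()]
    for i in range(K - 1):
        factor = 1.0 + w * scenario.temporal_profile[i] / 100.0
        if (factor <= 0).any():
            raise ValueError("growth factor <= 0; field would invert the surface")
        disp = (factor - 1.0)[:, None] * (clean[-1] - C)
        # local fold-over criterion: the displacement DIFFERENCE across an
        # edge must stay well below the edge length
        edge_vec = clean[-1][edges[:, 0]] - clean[-1][edges[:, 1]]
        edge_len = np.linalg.norm(edge_vec, axis=1)
        ddisp = np.linalg.norm(disp[edges[:, 0]] - disp[edges[:, 1]], axis=1)
        rel = ddisp / edge_len
        if rel.max() > 0.5:
            e = edges[int(rel.argmax())]
            raise ValueError(
                f"growth field too strong: differential displacement "
                f"{ddisp.max():.2f} mm across edge {tuple(e)} exceeds half "
                f"its length; surface may self-intersect "
                f"(max displacement {np.linalg.norm(disp, axis=1).max():.2f} mm)"
            )
        if (factor == 1.0).all():  # zero growth: bit-identical instance
            clean.append(clean[-1].copy())
        else:
            clean.append(C + factor[:, None] * (clean[-1] - C))

    times = np.arange(1, K + 1, dtype=float)
    noiseless = MeshSeries(
        [TriangleMesh(v, mesh.faces.copy(), f"T{i + 1}")
         for i, v in enumerate(clean)], times)
    noisy_meshes = []
    for i, m in enumerate(noiseless.meshes):
        eps = scenario.noise_sigma * rng.standard_normal(m.n_vertices)
        v = m.vertices + eps[:, None] * m.vertex_normals()
        noisy_meshes.append(TriangleMesh(v, mesh.faces.copy(), f"T{i + 1}"))
    series = MeshSeries(noisy_meshes, times)

    maps = [identity_correspondence(noiseless[i], f"T{i + 2}")
            for i in range(K - 1)]
    truth = compute_growth_field(noiseless, maps)
    return SyntheticSeries(template, scenario, series, noiseless, maps, truth)


def ground_truth_rates(scenario: GrowthScenario,
                       template: MandibleTemplate) -> GrowthField:
    """Ground-truth per-vertex rates, same shape/units as the pipeline output.

    Computed from the noiseless coordinates: the edge lengths of the growth
    map are known in closed form, so the rates are exact up to the shared
    spline-differentiation step.
    """
    quiet = GrowthScenario(region_rates=dict(scenario.region_rates),
                           n_instances=scenario.n_instances,
                           noise_sigma=0.0,
                           temporal_profile=scenario.temporal_profile.copy(),
                           smooth_iters=scenario.smooth_iters,
                           seed=scenario.seed)
    return grow_series(template, quiet).truth
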