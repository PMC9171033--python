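"""Normalized monthly morphological changes and spline-smoothed growth rates.

The change of an edge (a pair of adjacent vertices) from instance T_i to
T_{i+1} is the relative length increase normalized by the length at T_i, in
%/month, and is assigned to T_{i+1}.  A least-squares cubic smoothing spline
is fitted to the CUMULATIVE normalized change C(t) (C(T_1) = 0); the gradient
of the fitted curve at an instance is the instantaneous rate there.  Fitting
the cumulative curve (rather than the raw monthly changes) is what makes the
gradient carry %/month units: a constant monthly change c yields a linear C
whose gradient is exactly c at every instance.

Per-vertex rates are the unweighted mean over the incident edges; directional
anterior/posterior, superior/inferior, medial/lateral components distribute
each edge's rate by squared direction cosines, g_axis = g * (u . axis)^2,
which sums exactly back to g over the three axes.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline, make_smoothing_spline, splrep

from .correspondence import CorrespondenceMap
from .mesh import MeshSeries, TriangleMesh, mesh_edges


@dataclass
class GrowthCurve:
    """Fitted cumulative-change spline for one vertex pair."""

    spline: BSpline
    times: np.ndarray

    def cumulative(self, t) -> np.ndarray:
        return self.spline(t)

    def rate(self, t) -> np.ndarray:
        """Gradient of the cumulative curve (instantaneous rate, %/month)."""
        t = np.asarray(t, float)
        lo, hi = self.times[0], self.times[-1]
        if np.any(t < lo - 1e-12) or np.any(t > hi + 1e-12):
            raise ValueError(
                f"rate requested at t={t} outside fitted range [{lo}, {hi}]"
            )
        return self.spline.derivative()(t)


@dataclass
class EdgeGrowthTable:
    """Lengths and normalized monthly changes for every tracked edge.

    ``edges``: (E, 2) vertex pairs on the first mesh; ``lengths``: (E, K) mm;
    ``changes``: (E, K-1) %/month, column i holding the change assigned to
    instance i+1.
    """

    edges: np.ndarray
    times: np.ndarray
    lengths: np.ndarray
    changes: np.ndarray

    def __post_init__(self):
        if (self.lengths <= 0).any():
            bad = np.argwhere(self.lengths <= 0)[0]
            a, b = self.edges[bad[0]]
            raise ValueError(
                f"non-positive length for edge ({a}, {b}) at instance {bad[1]}"
            )
        if not np.isfinite(self.changes).all():
            raise ValueError("non-finite normalized change")


@dataclass
class GrowthField:
    """Per-vertex instantaneous rates (%/month) at every instance.

    ``total`` has shape (n, K); the directional components ``ap``/``si``/``ml``
    sum to ``total`` within 1e-9 by the squared-cosine decomposition.
    """

    times: np.ndarray
    total: np.ndarray
    ap: Optional[np.ndarray] = None
    si: Optional[np.ndarray] = None
    ml: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.ap is not None:
            s = self.ap + self.si + self.ml
            if np.abs(s - self.total).max() > 1e-9:
                raise ValueError("directional components do not sum to the total rate")

    @property
    def n_vertices(self) -> int:
        return self.total.shape[0]

    def component(self, name: str) -> np.ndarray:
        out = {"total": self.total, "ap": self.ap, "si": self.si,
               "ml": self.ml}[name]
        if out is None:
            raise ValueError(f"component {name!r} was not computed")
        return out

    def to_dataframe(self) -> pd.DataFrame:
        n, K = self.total.shape
        v, t = np.meshgrid(np.arange(n), np.arange(K), indexing="ij")
        d = {"vertex_index": v.ravel(), "instance": t.ravel() + 1,
             "rate": self.total.ravel()}
        for name in ("ap", "si", "ml"):
            arr = getattr(self, name)
            if arr is not None:
                d[name] = arr.ravel()
        return pd.DataFrame(d)

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# -- tracking ---------------------------------------------------------------

def track_indices(maps: Sequence[CorrespondenceMap], n: int) -> np.ndarray:
    """(n, K) matrix of the index of each first-instance vertex at every instance."""
    K = len(maps) + 1
    out = np.empty((n, K), np.int64)
    out[:, 0] = np.arange(n)
    for i, m in enumerate(maps):
        if m.n_source < out[:, i].max() + 1:
            raise ValueError(f"map {i} too small for tracked indices")
        out[:, i + 1] = m.target_index[out[:, i]]
    return out


def edge_length_changes(series: MeshSeries, maps: Sequence[CorrespondenceMap],
                        edges: Optional[np.ndarray] = None,
                        on_zero_length: str = "error") -> EdgeGrowthTable:
    """Track every edge of the first mesh through the correspondence chain.

    Records the edge length at each instance and the normalized monthly change
    g_i = 100 (L(T_{i+1}) - L(T_i)) / L(T_i), assigned to instance T_{i+1}.

    When consecutive models are independent reconstructions (e.g. decimated
    separately), several source vertices may legitimately snap to one target
    vertex and an edge can collapse to zero length; ``on_zero_length="drop"``
    removes such edges from the table instead of raising.
    """
    if len(maps) != len(series) - 1:
        raise ValueError("need exactly one correspondence map per interval")
    if on_zero_length not in ("error", "drop"):
        raise ValueError("on_zero_length must be 'error' or 'drop'")
    first = series[0]
    if edges is None:
        edges = mesh_edges(first)
    edges = np.asarray(edges, np.int64)
    chain = track_indices(maps, first.n_vertices)
    K = len(series)
    E = len(edges)
    L = np.empty((E, K))
    for i in range(K):
        pts = series[i].vertices
        ia = chain[edges[:, 0], i]
        ib = chain[edges[:, 1], i]
        L[:, i] = np.linalg.norm(pts[ia] - pts[ib], axis=1)
    if on_zero_length == "drop":
        keep = (L > 0).all(axis=1)
        edges, L = edges[keep], L[keep]
    with np.errstate(divide="ignore", invalid="ignore"):
        changes = 100.0 * np.diff(L, axis=1) / L[:, :-1]
    return EdgeGrowthTable(edges, np.asarray(series.times, float), L, changes)


# -- spline fitting ---------------------------------------------------------

def fit_growth_curve(times: np.ndarray, changes: np.ndarray,
                     smoothing: Optional[float] = None) -> GrowthCurve:
    """Least-squares cubic smoothing spline of cumulative change versus time.

    ``changes`` are the K-1 normalized monthly changes; the cumulative curve
    starts at 0.  With the default ``smoothing=None`` a penalized
    least-squares cubic spline is fitted with the penalty chosen by
    generalized cross-validation — measurement noise in the instance
    geometries would otherwise be amplified by differentiating an exact
    interpolant, worst at the series endpoints.  Noise-free data have zero
    residual at zero penalty, so GCV reproduces exact curves (a constant
    monthly change always returns exactly that constant rate).
    ``smoothing=0`` forces exact interpolation; a positive value is passed
    to FITPACK as the residual bound s.
    """
    times = np.asarray(times, float)
    changes = np.asarray(changes, float)
    if len(times) < 4:
        raise ValueError("cubic spline needs at least 4 instances")
    if len(changes) != len(times) - 1:
        raise ValueError("need exactly one change per interval")
    C = np.concatenate([[0.0], np.cumsum(changes)])
    if smoothing is None and len(times) >= 5:
        spline = make_smoothing_spline(times, C)
        return GrowthCurve(spline, times)
    s = 0.0 if smoothing is None else smoothing
    tck = splrep(times, C, k=3, s=s)
    return GrowthCurve(BSpline(*tck), times)


def rate_at_instance(curve: GrowthCurve, t: float) -> float:
    """Gradient of the fitted cumulative curve at instance time ``t`` (%/month)."""
    return float(curve.rate(t))


def edge_rates(table: EdgeGrowthTable,
               smoothing: Optional[float] = None) -> np.ndarray:
    """(E, K) instantaneous rates of every edge at every instance."""
    E, K = table.lengths.shape
    out = np.empty((E, K))
    for e in range(E):
        curve = fit_growth_curve(table.times, table.changes[e], smoothing)
        out[e] = curve.rate(table.times)
    return out


# -- per-vertex aggregation -------------------------------------------------

def _incidence(edges: np.ndarray, n: int):
    deg = np.zeros(n)
    np.add.at(deg, edges[:, 0], 1)
    np.add.at(deg, edges[:, 1], 1)
    if (deg == 0).any():
        isolated = np.flatnonzero(deg == 0)
        raise ValueError(f"isolated vertices with no incident edge: {isolated[:5]}")
    return deg


def vertex_rates(edge_rate_matrix: np.ndarray, edges: np.ndarray,
                 n_vertices: int) -> np.ndarray:
    """Per-vertex rate = unweighted mean over the edges incident to the vertex."""
    deg = _incidence(edges, n_vertices)
    acc = np.zeros((n_vertices, edge_rate_matrix.shape[1]))
    np.add.at(acc, edges[:, 0], edge_rate_matrix)
    np.add.at(acc, edges[:, 1], edge_rate_matrix)
    return acc / deg[:, None]


def directional_decompose(edge_rate_matrix: np.ndarray, edges: np.ndarray,
                          mesh: TriangleMesh, frame) -> dict:
    """Split edge rates into A/P, S/I, M/L components by squared direction cosines.

    ``frame`` is an anatomical frame (object with an ``axes`` (3, 3) array of
    unit row vectors ap, si, ml) or such an array directly.  Edge directions
    are taken from the first-instance geometry.  For each edge with unit
    direction u, the component along axis a is g (u . a)^2; the three
    components of every edge sum to g exactly since sum of squared direction
    cosines is 1 for an orthonormal frame.
    """
    axes = np.asarray(getattr(frame, "axes", frame), float)
    if axes.shape != (3, 3):
        raise ValueError("frame must provide a (3, 3) axes array")
    vec = mesh.vertices[edges[:, 1]] - mesh.vertices[edges[:, 0]]
    norm = np.linalg.norm(vec, axis=1)
    if (norm == 0).any():
        raise ValueError("zero-length edge; direction undefined")
    u = vec / norm[:, None]
    cos2 = (u @ axes.T) ** 2  # (E, 3)
    # renormalize so the decomposition is conservative to machine precision
    cos2 = cos2 / cos2.sum(axis=1, keepdims=True)
    return {name: edge_rate_matrix * cos2[:, [k]]
            for k, name in enumerate(("ap", "si", "ml"))}


def compute_growth_field(series: MeshSeries,
                         maps: Sequence[CorrespondenceMap],
                         frame=None, smoothing: Optional[float] = None,
                         edges: Optional[np.ndarray] = None) -> GrowthField:
    """End-to-end: edge tracking, spline rates, vertex means, directional split.

    Without a frame the package axes convention is used: x = medial/lateral,
    y = anterior/posterior, z = superior/inferior.
    """
    table = edge_length_changes(series, maps, edges)
    er = edge_rates(table, smoothing)
    n = series[0].n_vertices
    if frame is None:
        frame = np.array([[0.0, 1.0, 0.0],    # AP = +y
                          [0.0, 0.0, 1.0],    # SI = +z
                          [1.0, 0.0, 0.0]])   # ML = +x
    comps = directional_decompose(er, table.edges, series[0], frame)
    per_vertex = {k: vertex_rates(v, table.edges, n) for k, v in comps.items()}
    total_from_comps = sum(per_vertex.values())
    return GrowthField(times=table.times, total=total_from_comps,
                       ap=per_vertex["ap"], si=per_vertex["si"],
                       ml=per_vertex["ml"])
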