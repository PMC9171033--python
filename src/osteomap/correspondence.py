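"""Per-vertex correspondence between consecutive bone-surface models.

For every vertex j of the model at instance T_i the matching vertex on the
model at T_{i+1} is the candidate whose local neighborhood, after a local
rigid alignment (rotation R, translation v), maximizes the correlation
coefficient

    f = cov(Q_i, Q_{i+1}) / (sigma_i * sigma_{i+1})

between the neighborhood point sets Q around the vertex on the two models.
Because the two neighborhoods generally have different cardinalities, each
transformed source point is paired with its nearest target point and the
correlation is taken over the two concatenated, own-centroid-centered
coordinate vectors, which makes cov and the sigmas well defined.

The search is two-stage: one global rigid pre-alignment per model pair
(iterative closest point with Kabsch updates), then a discrete candidate
search around each pre-aligned vertex with a local Kabsch refinement per
candidate.  Candidate ties are broken deterministically (smaller distance to
the pre-aligned position, then smaller index) so results are bit-stable.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import (ChainMismatchError, NoCandidateError,
                     UndefinedScoreError)
from .mesh import TriangleMesh
from .rigid import RigidTransform, kabsch


@dataclass(frozen=True)
class Neighborhood:
    """Vertices within radius ``r`` (mm) of a center vertex, center included."""

    center_index: int
    points: np.ndarray  # (k, 3)
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "points",
                           np.asarray(self.points, float).reshape(-1, 3))
        if len(self.points) < 1:
            raise ValueError("neighborhood must contain at least its center")


@dataclass(frozen=True)
class VertexMatch:
    source_index: int
    target_index: int
    transform: RigidTransform
    score: float

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.score <= 1.0 + 1e-12:
            raise ValueError(f"correlation score {self.score} outside [-1, 1]")


@dataclass
class ICPResult:
    transform: RigidTransform
    rms: float
    n_iter: int


@dataclass
class CorrespondenceParams:
    """Search parameters.

    ``r``: neighborhood radius (mm); default 5x the source mean edge length so
    the correlation sees several vertex rings.  ``rho``: candidate search
    radius around the pre-aligned position; default 3x the mean edge length.
    ``score_tol``: discrimination floor of the correlation.  After local
    rigid refinement, score differences between nearby candidates are
    dominated by neighborhood-truncation artifacts (vertices entering or
    leaving the r-ball at its boundary) and are of order 1e-3, carrying no
    geometric information; candidates within ``score_tol`` of the best score
    are therefore treated as tied and resolved by distance to the
    pre-aligned position, then index.
    """

    r: Optional[float] = None
    rho: Optional[float] = None
    icp_max_iter: int = 50
    icp_tol: float = 1e-8
    refine_iters: int = 5
    score_tol: float = 5e-3
    # Candidate (target) neighborhoods use radius r * target_radius_factor:
    # the target ball must contain the grown/deformed image of the whole
    # source patch, otherwise the true candidate loses correlation to
    # boundary truncation while an offset candidate that happens to cover
    # the image scores perfectly (the correlation is scale-invariant).
    # Extra target points only serve as pairing candidates; they never enter
    # the correlation unpaired.
    target_radius_factor: float = 1.3


@dataclass
class CorrespondenceMap:
    """One matched target vertex (with local rigid transform and score) per source vertex."""

    source_label: Optional[str]
    target_label: Optional[str]
    target_index: np.ndarray        # (n,)
    score: np.ndarray               # (n,)
    rotations: np.ndarray           # (n, 3, 3)
    translations: np.ndarray        # (n, 3)
    pre_align: RigidTransform
    n_target: int

    def __post_init__(self):
        self.target_index = np.asarray(self.target_index, np.int64)
        self.score = np.asarray(self.score, float)
        if not np.isfinite(self.score).all():
            raise ValueError("non-finite correspondence scores")
        if self.target_index.min() < 0 or self.target_index.max() >= self.n_target:
            raise ValueError("matched index out of range on target mesh")

    @property
    def n_source(self) -> int:
        return len(self.target_index)

    def transform_of(self, j: int) -> RigidTransform:
        return RigidTransform(self.rotations[j], self.translations[j],
                              _validated=True)

    def to_dataframe(self) -> pd.DataFrame:
        n = self.n_source
        rot = self.rotations.reshape(n, 9)
        cols = {f"r{i}{k}": rot[:, 3 * i + k] for i in range(3) for k in range(3)}
        return pd.DataFrame({
            "source_index": np.arange(n),
            "target_index": self.target_index,
            "score": self.score,
            **cols,
            "t0": self.translations[:, 0],
            "t1": self.translations[:, 1],
            "t2": self.translations[:, 2],
        })

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self) -> str:
        return json.dumps({
            "source_label": self.source_label,
            "target_label": self.target_label,
            "n_target": self.n_target,
            "pre_align": {"rotation": self.pre_align.rotation.tolist(),
                          "translation": self.pre_align.translation.tolist()},
            "target_index": self.target_index.tolist(),
            "score": self.score.tolist(),
            "rotations": self.rotations.tolist(),
            "translations": self.translations.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "CorrespondenceMap":
        d = json.loads(text)
        return cls(
            source_label=d["source_label"], target_label=d["target_label"],
            target_index=np.asarray(d["target_index"], np.int64),
            score=np.asarray(d["score"], float),
            rotations=np.asarray(d["rotations"], float),
            translations=np.asarray(d["translations"], float),
            pre_align=RigidTransform(np.asarray(d["pre_align"]["rotation"]),
                                     np.asarray(d["pre_align"]["translation"])),
            n_target=int(d["n_target"]),
        )


# -- global pre-alignment ---------------------------------------------------

def global_align(source: TriangleMesh, target: TriangleMesh,
                 max_iter: int = 50, tol: float = 1e-8) -> ICPResult:
    """Rigid pre-alignment by iterative closest point with Kabsch updates.

    Minimizes the mean nearest-neighbor point-to-point distance of the source
    vertices to the target surface vertices; converged when the RMS change
    falls below ``tol``.
    """
    src = source.vertices
    tree = cKDTree(target.vertices)
    T = RigidTransform.identity()
    prev_rms = np.inf
    rms = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        x = T.apply(src)
        d, idx = tree.query(x)
        rms = float(np.sqrt((d ** 2).mean()))
        T = kabsch(src, target.vertices[idx], check_degenerate=True)
        if abs(prev_rms - rms) < tol:
            break
        prev_rms = rms
    d, _ = tree.query(T.apply(src))
    return ICPResult(T, float(np.sqrt((d ** 2).mean())), it)


# -- correlation score ------------------------------------------------------

def neighborhood_correlation(q_src: Neighborhood, q_tgt: Neighborhood,
                             transform: RigidTransform,
                             _tgt_tree: Optional[cKDTree] = None) -> float:
    """Correlation f = cov/(sigma_src sigma_tgt) of two matched neighborhoods.

    The source points are moved by ``transform``, paired each with its nearest
    target point, both matched lists are centered on their own centroids, and
    the Pearson correlation of the two concatenated length-3m coordinate
    vectors is returned (in [-1, 1] by Cauchy-Schwarz).
    """
    if len(q_src.points) < 2 or len(q_tgt.points) < 2:
        raise ValueError("neighborhood correlation needs >= 2 points on each side")
    X = transform.apply(q_src.points)
    tree = _tgt_tree if _tgt_tree is not None else cKDTree(q_tgt.points)
    _, idx = tree.query(X)
    Y = q_tgt.points[idx]
    x = (X - X.mean(axis=0)).ravel()
    y = (Y - Y.mean(axis=0)).ravel()
    vx = float((x * x).mean())
    vy = float((y * y).mean())
    if vx == 0.0 or vy == 0.0:
        raise UndefinedScoreError(
            "zero variance in a matched neighborhood; correlation undefined"
        )
    # single sqrt of the variance product so a perfect copy scores exactly 1
    score = float((x * y).mean() / np.sqrt(vx * vy))
    score = min(1.0, max(-1.0, score))
    if abs(score - 1.0) < 1e-13:
        score = 1.0
    elif abs(score + 1.0) < 1e-13:
        score = -1.0
    return score


def _score_candidates(q_src_pts: np.ndarray, cand_pts: np.ndarray,
                      cand_sizes: np.ndarray, R0: np.ndarray,
                      t0: np.ndarray, refine_iters: int):
    """Vectorized local Kabsch refinement + correlation over C candidates.

    ``cand_pts`` is (C, M, 3), padded beyond each candidate's ``cand_sizes``
    entries with a far-away sentinel that never wins a nearest-neighbor
    query.  ``R0``/``t0`` hold the per-candidate initial transforms.  Returns
    (scores, rotations, translations); a candidate with an undefined
    correlation (zero variance) gets score NaN.
    """
    C, M, _ = cand_pts.shape
    P = q_src_pts                                   # (m, 3), shared
    m = len(P)
    R = R0.copy()                                   # (C, 3, 3)
    t = t0.copy()                                   # (C, 3)
    yy = (cand_pts ** 2).sum(-1)                    # (C, M)
    cand_T = np.ascontiguousarray(cand_pts.transpose(0, 2, 1))
    cp = P.mean(axis=0)
    Pc = P - cp

    def nearest(R, t):
        X = np.matmul(P[None, :, :], R.transpose(0, 2, 1)) + t[:, None, :]
        xx = (X ** 2).sum(-1)
        d2 = np.matmul(X, cand_T)
        d2 *= -2.0
        d2 += xx[:, :, None]
        d2 += yy[:, None, :]
        return X, d2.argmin(axis=2)

    prev_idx = None
    stable = False
    for _ in range(max(refine_iters, 0)):
        X, idx = nearest(R, t)
        if prev_idx is not None and np.array_equal(idx, prev_idx):
            stable = True
            break
        prev_idx = idx
        Y = np.take_along_axis(cand_pts, idx[:, :, None], axis=1)  # (C, m, 3)
        cq = Y.mean(axis=1)
        H = np.matmul(Pc.T[None, :, :], Y - cq[:, None, :])        # (C, 3, 3)
        U, S, Vt = np.linalg.svd(H)
        UT = U.transpose(0, 2, 1)
        d = np.sign(np.linalg.det(np.matmul(Vt.transpose(0, 2, 1), UT)))
        d[d == 0] = 1.0
        Vt2 = Vt.copy()
        Vt2[:, 2, :] *= d[:, None]
        R = np.matmul(Vt2.transpose(0, 2, 1), UT)
        t = cq - np.einsum("cij,j->ci", R, cp)
    if not stable:  # transform moved after the last pairing
        X, idx = nearest(R, t)
    Y = np.take_along_axis(cand_pts, idx[:, :, None], axis=1)
    x = (X - X.mean(axis=1, keepdims=True)).reshape(C, 3 * m)
    y = (Y - Y.mean(axis=1, keepdims=True)).reshape(C, 3 * m)
    vx = (x * x).mean(axis=1)
    vy = (y * y).mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        # single sqrt of the variance product so x == y scores exactly 1
        scores = (x * y).mean(axis=1) / np.sqrt(vx * vy)
    scores = np.where((vx == 0) | (vy == 0), np.nan, scores)
    scores = np.clip(scores, -1.0, 1.0)
    # a perfect copy must score exactly +/-1; absorb SVD round-off
    scores[np.abs(scores - 1.0) < 1e-13] = 1.0
    scores[np.abs(scores + 1.0) < 1e-13] = -1.0
    return scores, R, t


# -- per-vertex matching ----------------------------------------------------

class _PairContext:
    """Precomputed KD-trees and neighborhoods for one (source, target) pair."""

    def __init__(self, source: TriangleMesh, target: TriangleMesh, r: float,
                 r_target: Optional[float] = None):
        self.source = source
        self.target = target
        self.r = r
        self.r_target = r_target if r_target is not None else r
        self.tgt_tree = cKDTree(target.vertices)
        src_tree = cKDTree(source.vertices)
        self.src_neigh = src_tree.query_ball_point(source.vertices, r)
        self.tgt_neigh = self.tgt_tree.query_ball_point(target.vertices,
                                                        self.r_target)
        self._tgt_pts_cache: dict[int, np.ndarray] = {}

    def target_points(self, c: int) -> np.ndarray:
        pts = self._tgt_pts_cache.get(c)
        if pts is None:
            idx = np.array(sorted(self.tgt_neigh[c]), np.int64)
            pts = self.target.vertices[idx]
            self._tgt_pts_cache[c] = pts
        return pts

    def padded_candidates(self, cand: np.ndarray):
        """(C, M, 3) candidate neighborhoods, padded far away, plus sizes.

        The padding sentinel (1e9 mm) is finite so BLAS distance computations
        stay NaN-free, yet can never win a nearest-neighbor query.
        """
        pts = [self.target_points(int(c)) for c in cand]
        sizes = np.array([len(p) for p in pts])
        M = sizes.max()
        out = np.full((len(cand), M, 3), 1e9)
        for k, p in enumerate(pts):
            out[k, :len(p)] = p
        return out, sizes


def match_vertex(source: TriangleMesh, target: TriangleMesh, j: int,
                 r: float, rho: float, pre_align: RigidTransform,
                 refine_iters: int = 5, score_tol: float = 5e-3,
                 target_radius_factor: float = 1.3,
                 _ctx: Optional[_PairContext] = None) -> VertexMatch:
    """Find the target vertex corresponding to source vertex ``j``.

    Candidate centers are the target vertices within ``rho`` of the
    pre-aligned position of P_j (``rho`` may be ``np.inf`` for an exhaustive
    search).  For each candidate a local rigid transform is refined by Kabsch
    on nearest-neighbor pairings (at most ``refine_iters`` passes) and the
    neighborhood correlation computed; the candidate with the highest score
    wins.  Scores within ``score_tol`` of the best are ties (differences
    below the correlation's discrimination floor), broken by distance to the
    pre-aligned position and then by index.
    """
    if r <= 0 or rho <= 0:
        raise ValueError("radii r and rho must be positive")
    if not 0 <= j < source.n_vertices:
        raise IndexError(f"vertex {j} out of range")
    ctx = _ctx if _ctx is not None else _PairContext(
        source, target, r, r * target_radius_factor)
    p0 = pre_align.apply(source.vertices[j])
    if np.isinf(rho):
        cand = np.arange(target.n_vertices)
    else:
        cand = np.array(sorted(ctx.tgt_tree.query_ball_point(p0, rho)), np.int64)
    if len(cand) == 0:
        raise NoCandidateError(j, rho)

    q_src_pts = source.vertices[np.array(ctx.src_neigh[j], np.int64)]
    if len(q_src_pts) < 2:
        raise UndefinedScoreError(
            f"source neighborhood of vertex {j} has < 2 points; enlarge r"
        )
    cand_pts, sizes = ctx.padded_candidates(cand)
    R0 = np.broadcast_to(pre_align.rotation, (len(cand), 3, 3)).copy()
    t0 = pre_align.translation + (target.vertices[cand] - p0)
    scores, R, t = _score_candidates(q_src_pts, cand_pts, sizes, R0, t0,
                                     refine_iters)
    valid = np.isfinite(scores)
    if not valid.any():
        raise NoCandidateError(j, rho)
    dist = np.linalg.norm(target.vertices[cand] - p0, axis=1)
    top = np.nanmax(np.where(valid, scores, -np.inf))
    tied = valid & (scores >= top - score_tol)
    # among tied candidates: smallest distance, then smallest index
    order = np.lexsort((cand, dist))
    best = order[tied[order]][0]
    c = int(cand[best])
    T = RigidTransform(R[best], t[best], _validated=True)
    return VertexMatch(j, c, T, float(scores[best]))


def build_correspondence(source: TriangleMesh, target: TriangleMesh,
                         params: Optional[CorrespondenceParams] = None
                         ) -> CorrespondenceMap:
    """Global pre-alignment followed by a per-vertex local correlation search."""
    params = params or CorrespondenceParams()
    mel = source.mean_edge_length()
    r = params.r if params.r is not None else 5.0 * mel
    rho = params.rho if params.rho is not None else 3.0 * mel
    icp = global_align(source, target, params.icp_max_iter, params.icp_tol)
    ctx = _PairContext(source, target, r, r * params.target_radius_factor)
    n = source.n_vertices
    tgt_idx = np.empty(n, np.int64)
    scores = np.empty(n, float)
    rots = np.empty((n, 3, 3), float)
    trans = np.empty((n, 3), float)
    for j in range(n):
        try:
            m = match_vertex(source, target, j, r, rho, icp.transform,
                             params.refine_iters, params.score_tol, _ctx=ctx)
        except NoCandidateError as e:
            raise NoCandidateError(j, rho) from e
        tgt_idx[j] = m.target_index
        scores[j] = m.score
        rots[j] = m.transform.rotation
        trans[j] = m.transform.translation
    return CorrespondenceMap(
        source_label=source.instance_label, target_label=target.instance_label,
        target_index=tgt_idx, score=scores, rotations=rots, translations=trans,
        pre_align=icp.transform, n_target=target.n_vertices,
    )


def compose_correspondence(maps: Sequence[CorrespondenceMap]) -> CorrespondenceMap:
    """Chain i -> i+1 maps into a first-to-last map by following matched indices.

    The composed local transform is the composition along the chain; the
    composed score is the minimum score met along the chain (the weakest link).
    """
    if len(maps) == 0:
        raise ValueError("need at least one map")
    for a, b in zip(maps[:-1], maps[1:]):
        if a.n_target != b.n_source:
            raise ChainMismatchError(
                f"map {a.source_label}->{a.target_label} has {a.n_target} target "
                f"vertices but next map has {b.n_source} source vertices"
            )
        if (a.target_label is not None and b.source_label is not None
                and a.target_label != b.source_label):
            raise ChainMismatchError(
                f"labels do not chain: {a.target_label!r} != {b.source_label!r}"
            )
    n = maps[0].n_source
    idx = np.arange(n)
    score = np.full(n, np.inf)
    rots = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
    trans = np.zeros((n, 3))
    pre = maps[0].pre_align
    for m in maps:
        score = np.minimum(score, m.score[idx])
        rots = np.einsum("nij,njk->nik", m.rotations[idx], rots)
        trans = np.einsum("nij,nj->ni", m.rotations[idx], trans) \
            + m.translations[idx]
        idx = m.target_index[idx]
    return CorrespondenceMap(
        source_label=maps[0].source_label, target_label=maps[-1].target_label,
        target_index=idx, score=score, rotations=rots, translations=trans,
        pre_align=pre, n_target=maps[-1].n_target,
    )


def identity_correspondence(mesh: TriangleMesh,
                            target_label: Optional[str] = None
                            ) -> CorrespondenceMap:
    """The identity map of a mesh onto an equally indexed mesh (score 1 everywhere)."""
    n = mesh.n_vertices
    return CorrespondenceMap(
        source_label=mesh.instance_label, target_label=target_label,
        target_index=np.arange(n), score=np.ones(n),
        rotations=np.broadcast_to(np.eye(3), (n, 3, 3)).copy(),
        translations=np.zeros((n, 3)),
        pre_align=RigidTransform.identity(), n_target=n,
    )
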