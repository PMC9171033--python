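"""Quadric error-metric edge-collapse simplification.

Garland-Heckbert style: each vertex carries the sum of the squared-distance
quadrics of its incident face planes (area weighted); edges are collapsed in
order of increasing quadric cost at the optimal contraction point.  Collapses
that would break local manifoldness (link condition) or flip a surviving face
normal are rejected, which preserves watertightness of closed inputs.  Each
accepted collapse removes exactly one vertex, so any target count down to 4 is
reachable exactly on well-behaved meshes.
"""
from __future__ import annotations

import heapq
import itertools

import numpy as np


def _face_quadrics(V: np.ndarray, F: np.ndarray) -> np.ndarray:
    p0, p1, p2 = V[F[:, 0]], V[F[:, 1]], V[F[:, 2]]
    n = np.cross(p1 - p0, p2 - p0)
    area2 = np.linalg.norm(n, axis=1)  # 2 * area
    safe = np.where(area2 > 0, area2, 1.0)
    nu = n / safe[:, None]
    d = -np.einsum("ij,ij->i", nu, p0)
    plane = np.concatenate([nu, d[:, None]], axis=1)  # (m, 4)
    K = plane[:, :, None] * plane[:, None, :]  # (m, 4, 4)
    return K * (0.5 * area2)[:, None, None]


def _optimal_point(Q: np.ndarray, va: np.ndarray, vb: np.ndarray):
    A = Q[:3, :3]
    b = -Q[:3, 3]
    try:
        if np.linalg.cond(A) < 1e7:
            v = np.linalg.solve(A, b)
        else:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        v = None
    candidates = [va, vb, 0.5 * (va + vb)]
    if v is not None:
        candidates.insert(0, v)
    best, best_cost = None, np.inf
    for c in candidates:
        h = np.append(c, 1.0)
        cost = float(h @ Q @ h)
        if cost < best_cost:
            best, best_cost = c, cost
    return best, max(best_cost, 0.0)


def quadric_decimate(vertices: np.ndarray, faces: np.ndarray, target_n: int):
    """Simplify (vertices, faces) down to exactly ``target_n`` vertices.

    Returns ``(new_vertices, new_faces)``.  Raises ``RuntimeError`` if no valid
    collapse remains before the target is reached.
    """
    V = np.asarray(vertices, float).copy()
    F = np.asarray(faces, np.int64).copy()
    n = len(V)
    if not 4 <= target_n <= n:
        raise ValueError(f"target_n must be in [4, {n}], got {target_n}")

    quad = _face_quadrics(V, F)
    Qv = np.zeros((n, 4, 4))
    for k in range(3):
        np.add.at(Qv, F[:, k], quad)

    face_alive = np.ones(len(F), bool)
    vert_alive = np.ones(n, bool)
    vfaces = [set() for _ in range(n)]
    for fi, f in enumerate(F):
        for v in f:
            vfaces[v].add(fi)

    version = np.zeros(n, np.int64)
    counter = itertools.count()

    def neighbors(v):
        out = set()
        for fi in vfaces[v]:
            out.update(F[fi])
        out.discard(v)
        return out

    def push_edges_of(v):
        for u in neighbors(v):
            a, b = (v, u) if v < u else (u, v)
            pos, cost = _optimal_point(Qv[a] + Qv[b], V[a], V[b])
            heapq.heappush(heap, (cost, next(counter), a, b,
                                  version[a], version[b], pos))

    heap: list = []
    seen = set()
    for f in F:
        for i, j in ((0, 1), (1, 2), (2, 0)):
            a, b = int(f[i]), int(f[j])
            if a > b:
                a, b = b, a
            if (a, b) not in seen:
                seen.add((a, b))
                pos, cost = _optimal_point(Qv[a] + Qv[b], V[a], V[b])
                heapq.heappush(heap, (cost, next(counter), a, b, 0, 0, pos))
    del seen

    n_alive = n
    while n_alive > target_n:
        if not heap:
            raise RuntimeError(
                f"decimation stalled at {n_alive} vertices (target {target_n}): "
                "no valid edge collapse remains"
            )
        cost, _, a, b, va_ver, vb_ver, pos = heapq.heappop(heap)
        if not (vert_alive[a] and vert_alive[b]):
            continue
        if version[a] != va_ver or version[b] != vb_ver:
            continue
        shared = vfaces[a] & vfaces[b]
        # Link condition: common vertex neighbors must all be apexes of shared
        # faces, otherwise the collapse pinches the surface.
        common = neighbors(a) & neighbors(b)
        apexes = set()
        for fi in shared:
            apexes.update(int(x) for x in F[fi] if x != a and x != b)
        if common != apexes or len(shared) == 0:
            continue
        # Normal-flip / degeneracy check on surviving faces of both vertices.
        ok = True
        affected = (vfaces[a] | vfaces[b]) - shared
        for fi in affected:
            tri = F[fi]
            old = V[tri]
            new = old.copy()
            for k in range(3):
                if tri[k] == a or tri[k] == b:
                    new[k] = pos
            n_old = np.cross(old[1] - old[0], old[2] - old[0])
            n_new = np.cross(new[1] - new[0], new[2] - new[0])
            nn = np.linalg.norm(n_new)
            if nn < 1e-14 or np.dot(n_old, n_new) <= 0:
                ok = False
                break
        if not ok:
            continue

        # Collapse b into a at pos.
        V[a] = pos
        Qv[a] = Qv[a] + Qv[b]
        vert_alive[b] = False
        for fi in shared:
            face_alive[fi] = False
            for v in F[fi]:
                vfaces[v].discard(fi)
        for fi in list(vfaces[b]):
            F[fi][F[fi] == b] = a
            vfaces[a].add(fi)
            vfaces[b].discard(fi)
        version[a] += 1
        version[b] += 1
        n_alive -= 1
        push_edges_of(a)

    keep = np.flatnonzero(vert_alive)
    remap = -np.ones(n, np.int64)
    remap[keep] = np.arange(len(keep))
    newF = remap[F[face_alive]]
    return V[keep], newF
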