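"""Landmark-based validation and vertex-count sensitivity analysis.

Position accuracy: landmarks identified on the first-instance model are
snapped to their nearest mesh vertex and propagated through the
correspondence chain; the RMSE of the propagated positions against
gold-standard positions is reported per landmark and instance, with the
replicate axis (the study subjects) supplied explicitly.  Rate accuracy:
inter-landmark distances are turned into normalized monthly rates
100 (D(T_{i+1}) - D(T_i)) / D(T_i) and the RMSE of (estimated - gold) is
reported per pair and interval.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .anatomy import LandmarkSet, RegionLabels
from .correspondence import CorrespondenceMap, CorrespondenceParams, \
    build_correspondence
from .mesh import MeshSeries, decimate


def propagate_landmarks(landmarks: LandmarkSet, series: MeshSeries,
                        maps: Sequence[CorrespondenceMap]) -> list:
    """Track first-instance landmarks through the correspondence chain.

    Each landmark is snapped to the nearest vertex of the first mesh (a snap
    farther than 3x the mean edge length raises a warning — the landmark is
    off-surface); its position at T_k is the position of the tracked vertex on
    mesh k.  Returns one LandmarkSet per instance.
    """
    if len(maps) != len(series) - 1:
        raise ValueError("need one correspondence map per interval")
    first = series[0]
    tree = cKDTree(first.vertices)
    names = landmarks.names
    dist, vidx = tree.query(landmarks.positions(names))
    limit = 3.0 * first.mean_edge_length()
    for name, d in zip(names, dist):
        if d > limit:
            warnings.warn(
                f"landmark {name!r} snapped over {d:.2f} mm (> {limit:.2f} mm); "
                "it may lie off the surface", stacklevel=2)
    out = [LandmarkSet({n: first.vertices[v] for n, v in zip(names, vidx)})]
    cur = vidx.copy()
    for i, m in enumerate(maps):
        cur = m.target_index[cur]
        mesh = series[i + 1]
        out.append(LandmarkSet({n: mesh.vertices[v]
                                for n, v in zip(names, cur)}))
    return out


def _stack(replicates, names, K):
    """(R, L, K, 3) array from replicates of per-instance LandmarkSets."""
    arr = np.empty((len(replicates), len(names), K, 3))
    for r, inst_sets in enumerate(replicates):
        if len(inst_sets) != K:
            raise ValueError("replicates must cover the same instances")
        for k, ls in enumerate(inst_sets):
            arr[r, :, k, :] = ls.positions(names)
    return arr


def position_rmse(estimated: Sequence[Sequence[LandmarkSet]],
                  gold: Sequence[Sequence[LandmarkSet]]) -> pd.DataFrame:
    """Per-landmark, per-instance RMSE (mm) over replicates, plus Mean/SD margins.

    ``estimated`` and ``gold`` are sequences over replicates of sequences over
    instances of LandmarkSets with matching names.  Rows are landmarks with a
    trailing ``Mean``/``SD`` pair; columns T1..TK plus ``Mean``/``SD`` of each
    landmark's instance values.
    """
    if len(estimated) != len(gold) or len(estimated) == 0:
        raise ValueError("estimated and gold need the same, non-zero replicate count")
    names = estimated[0][0].names
    for rep in list(estimated) + list(gold):
        for ls in rep:
            if set(ls.names) != set(names):
                raise ValueError("landmark name mismatch between sets")
    K = len(estimated[0])
    E = _stack(estimated, names, K)
    G = _stack(gold, names, K)
    err = np.linalg.norm(E - G, axis=-1)            # (R, L, K)
    rmse = np.sqrt((err ** 2).mean(axis=0))         # (L, K)
    cols = [f"T{k + 1}" for k in range(K)]
    df = pd.DataFrame(rmse, index=names, columns=cols)
    df["Mean"] = rmse.mean(axis=1)
    df["SD"] = rmse.std(axis=1, ddof=1)
    bottom = pd.DataFrame(
        [rmse.mean(axis=0), rmse.std(axis=0, ddof=1)],
        index=["Mean", "SD"], columns=cols)
    return pd.concat([df, bottom])


def interlandmark_rates(sets: Sequence[LandmarkSet],
                        pairs: Sequence[tuple]) -> np.ndarray:
    """(P, K-1) normalized monthly rates of inter-landmark distances (%/month)."""
    K = len(sets)
    D = np.empty((len(pairs), K))
    for p, (a, b) in enumerate(pairs):
        for k, ls in enumerate(sets):
            D[p, k] = np.linalg.norm(ls[a] - ls[b])
    if (D == 0).any():
        raise ValueError("zero inter-landmark distance; rate undefined")
    return 100.0 * np.diff(D, axis=1) / D[:, :-1]


def rate_rmse(estimated: Sequence[Sequence[LandmarkSet]],
              gold: Sequence[Sequence[LandmarkSet]],
              pairs: Sequence[tuple]) -> pd.DataFrame:
    """RMSE (%/month) of inter-landmark rate changes against gold, per pair/interval."""
    if len(estimated) != len(gold) or len(estimated) == 0:
        raise ValueError("estimated and gold need the same, non-zero replicate count")
    K = len(estimated[0])
    E = np.stack([interlandmark_rates(rep, pairs) for rep in estimated])
    G = np.stack([interlandmark_rates(rep, pairs) for rep in gold])
    rmse = np.sqrt(((E - G) ** 2).mean(axis=0))     # (P, K-1)
    cols = [f"T{k + 1}-T{k + 2}" for k in range(K - 1)]
    labels = [f"{a}-{b}" for a, b in pairs]
    df = pd.DataFrame(rmse, index=labels, columns=cols)
    df["Mean"] = rmse.mean(axis=1)
    df["SD"] = rmse.std(axis=1, ddof=1)
    bottom = pd.DataFrame(
        [rmse.mean(axis=0), rmse.std(axis=0, ddof=1)],
        index=["Mean", "SD"], columns=cols)
    return pd.concat([df, bottom])


# -- vertex-count sensitivity ----------------------------------------------


@dataclass
class SensitivityResult:
    chosen_n: int
    trace: pd.DataFrame


def _region_changes(series: MeshSeries, labels: RegionLabels,
                    params: Optional[CorrespondenceParams]) -> np.ndarray:
    """Per-region mean rates, robust to edge collapses between the
    independently decimated models (collapsed edges are dropped; vertices
    left without a surviving edge are excluded from the region mean)."""
    from .growth import edge_length_changes, edge_rates

    maps = [build_correspondence(series[i], series[i + 1], params)
            for i in range(len(series) - 1)]
    table = edge_length_changes(series, maps, on_zero_length="drop")
    er = edge_rates(table)
    n = series[0].n_vertices
    deg = np.zeros(n)
    acc = np.zeros((n, er.shape[1]))
    np.add.at(deg, table.edges[:, 0], 1)
    np.add.at(deg, table.edges[:, 1], 1)
    np.add.at(acc, table.edges[:, 0], er)
    np.add.at(acc, table.edges[:, 1], er)
    with np.errstate(invalid="ignore", divide="ignore"):
        vr = acc / deg[:, None]
    out = []
    for region in sorted(set(labels.labels)):
        idx = np.flatnonzero(labels.labels == region)
        out.append(np.nanmean(vr[idx], axis=0))
    return np.concatenate(out)


def vertex_count_sensitivity(series: MeshSeries, labels: RegionLabels,
                             start_n: Optional[int] = None,
                             decrement_fraction: float = 0.05,
                             alpha: float = 0.05,
                             test: str = "ttest",
                             min_n: int = 50,
                             params: Optional[CorrespondenceParams] = None
                             ) -> SensitivityResult:
    """Scan decreasing vertex counts until regional changes differ significantly.

    The pipeline is run at ``start_n`` vertices (each instance decimated, region
    labels transferred by nearest vertex) as the reference, then at counts
    reduced by ``decrement_fraction`` of ``start_n`` per step.  At each step the
    per-region mean rates are compared to the reference with a paired two-sided
    test (paired t-test by default, ``test="wilcoxon"`` for the rank
    alternative).  The chosen count is the last one before the first
    significant difference; if the very first step is already significant the
    start count is returned with a warning.
    """
    if not 0 < decrement_fraction < 1:
        raise ValueError("decrement_fraction must be in (0, 1)")
    n0 = series[0].n_vertices
    start_n = start_n or n0
    if start_n > n0:
        raise ValueError(f"start_n {start_n} exceeds mesh vertex count {n0}")
    step = max(1, round(decrement_fraction * start_n))
    counts = list(range(start_n, max(min_n, 4) - 1, -step))
    if len(counts) < 2:
        raise ValueError("sensitivity scan needs at least two counts; lower min_n")

    tree = cKDTree(series[0].vertices)

    def run_at(count):
        meshes = [decimate(m, count) for m in series.meshes]
        sub = MeshSeries(meshes, series.times)
        _, near = tree.query(meshes[0].vertices)
        sub_labels = RegionLabels(labels.labels[near])
        return _region_changes(sub, sub_labels, params)

    ref = run_at(counts[0])
    rows = [{"count": counts[0], "pvalue": np.nan, "significant": False}]
    chosen = counts[-1]
    for k, count in enumerate(counts[1:], start=1):
        cur = run_at(count)
        diff = cur - ref
        if np.allclose(diff, 0):
            p = 1.0
        elif test == "ttest":
            p = float(stats.ttest_rel(cur, ref).pvalue)
        elif test == "wilcoxon":
            p = float(stats.wilcoxon(cur, ref).pvalue)
        else:
            raise ValueError(f"unknown test {test!r}")
        sig = p < alpha
        rows.append({"count": count, "pvalue": p, "significant": sig})
        if sig:
            if k == 1:
                warnings.warn(
                    "significant difference at the first decrement; "
                    "returning the start count", stacklevel=2)
                chosen = counts[0]
            else:
                chosen = counts[k - 1]
            break
    else:
        chosen = counts[-1]
    return SensitivityResult(chosen, pd.DataFrame(rows))
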