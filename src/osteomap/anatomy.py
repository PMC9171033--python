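"""Landmarks, anatomical frame, region labels, summaries and thickness metrics.

The 17 standard mandibular landmarks are the midline genial tubercle (GT)
plus, per side, the lateral/medial condylar poles (Cd-lat, Cd-med), coronoid
process (Cr), gonion (Go), three mental-foramen points (MF1-MF3) and the
genial fovea (GF).  Bilateral names carry an ``L_``/``R_`` prefix.

Region labels (six regions: condyle, posterior/anterior ramus,
posterior/middle/anterior corpus) are an input partition of the vertex set,
not computed here — outlining the regions on a specimen is a manual or
upstream step; the synthetic generator emits labels for testing.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Optional

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError
from .growth import GrowthField
from .mesh import TriangleMesh
from .rigid import RigidTransform

REGIONS = ("condyle", "posterior_ramus", "anterior_ramus",
           "posterior_corpus", "middle_corpus", "anterior_corpus")

_BILATERAL = ("Cd-lat", "Cd-med", "Cr", "Go", "MF1", "MF2", "MF3", "GF")
LANDMARK_NAMES = ("GT",) + tuple(f"{side}_{n}" for side in ("R", "L")
                                 for n in _BILATERAL)


class LandmarkSet:
    """Named 3D points in mm, with unique names."""

    def __init__(self, points: Dict[str, np.ndarray]):
        self._points = {}
        for name, p in points.items():
            p = np.asarray(p, float).reshape(3)
            if not np.isfinite(p).all():
                raise ValueError(f"non-finite coordinates for landmark {name!r}")
            if name in self._points:
                raise ValueError(f"duplicate landmark name {name!r}")
            self._points[str(name)] = p

    @property
    def names(self) -> list:
        return list(self._points)

    def __len__(self) -> int:
        return len(self._points)

    def __contains__(self, name) -> bool:
        return name in self._points

    def __getitem__(self, name) -> np.ndarray:
        if name not in self._points:
            raise KeyError(f"missing landmark {name!r}")
        return self._points[name]

    def positions(self, names: Optional[Iterable[str]] = None) -> np.ndarray:
        names = list(names) if names is not None else self.names
        return np.stack([self[n] for n in names])

    def transformed(self, transform: RigidTransform) -> "LandmarkSet":
        return LandmarkSet({n: transform.apply(p)
                            for n, p in self._points.items()})

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_csv(cls, path) -> "LandmarkSet":
        df = pd.read_csv(path)
        missing = {"name", "x", "y", "z"} - set(df.columns)
        if missing:
            raise ValueError(f"landmark CSV missing columns: {sorted(missing)}")
        if df["name"].duplicated().any():
            dups = df.loc[df["name"].duplicated(), "name"].tolist()
            raise ValueError(f"duplicate landmark names in CSV: {dups}")
        return cls({row["name"]: np.array([row.x, row.y, row.z])
                    for _, row in df.iterrows()})

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [{"name": n, "x": p[0], "y": p[1], "z": p[2]}
             for n, p in self._points.items()]
        ).to_csv(path, index=False, float_format="%.12g")

    def to_dict(self) -> Dict[str, np.ndarray]:
        return dict(self._points)


@dataclass(frozen=True)
class AnatomicalFrame:
    """Orthonormal right-handed anatomical axes (unit row vectors) plus origin."""

    origin: np.ndarray
    ap: np.ndarray
    si: np.ndarray
    ml: np.ndarray

    def __post_init__(self):
        for name in ("origin", "ap", "si", "ml"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), float).reshape(3))
        A = self.axes
        if np.abs(A @ A.T - np.eye(3)).max() > 1e-9:
            raise DegenerateGeometryError("frame axes not orthonormal")
        if np.linalg.det(np.stack([self.ap, self.si, self.ml])) < 0:
            raise DegenerateGeometryError("frame is left-handed")

    @property
    def axes(self) -> np.ndarray:
        """Rows ap, si, ml — the layout growth.directional_decompose expects."""
        return np.stack([self.ap, self.si, self.ml])

    @classmethod
    def canonical(cls) -> "AnatomicalFrame":
        return cls(np.zeros(3), [0, 1, 0], [0, 0, 1], [1, 0, 0])


def build_frame(landmarks: LandmarkSet) -> AnatomicalFrame:
    """Anatomical frame from landmarks.

    ML is the inter-condylar (lateral pole) direction, AP points from the
    gonion midpoint to the genial tubercle (orthogonalized against ML),
    SI = ML x AP, and the origin is the gonion midpoint.  Requires both
    Cd-lat, both Go, and GT.
    """
    for name in ("L_Cd-lat", "R_Cd-lat", "L_Go", "R_Go", "GT"):
        if name not in landmarks:
            raise KeyError(f"missing required landmark {name!r}")
    ml = landmarks["L_Cd-lat"] - landmarks["R_Cd-lat"]
    scale = np.linalg.norm(ml)
    if scale < 1e-12:
        raise DegenerateGeometryError("coincident condylar poles; ML undefined")
    ml = ml / scale
    origin = 0.5 * (landmarks["L_Go"] + landmarks["R_Go"])
    ap = landmarks["GT"] - origin
    ap = ap - (ap @ ml) * ml
    if np.linalg.norm(ap) < 1e-9 * max(scale, 1.0):
        raise DegenerateGeometryError(
            "GT, gonion midpoint and ML axis are collinear; AP undefined"
        )
    ap = ap / np.linalg.norm(ap)
    si = np.cross(ml, ap)
    return AnatomicalFrame(origin, ap, si, ml)


# -- region labels ----------------------------------------------------------

class RegionLabels:
    """Per-vertex region label; a partition of the vertex set."""

    def __init__(self, labels: np.ndarray):
        self.labels = np.asarray(labels, dtype=object).astype(str)
        unknown = set(self.labels) - set(REGIONS)
        if unknown:
            raise ValueError(f"unknown region labels: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.labels)

    def indices(self, region: str) -> np.ndarray:
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        return np.flatnonzero(self.labels == region)

    def counts(self) -> Dict[str, int]:
        return {r: int((self.labels == r).sum()) for r in REGIONS}

    @classmethod
    def from_csv(cls, path) -> "RegionLabels":
        df = pd.read_csv(path)
        missing = {"vertex_index", "label"} - set(df.columns)
        if missing:
            raise ValueError(f"label CSV missing columns: {sorted(missing)}")
        df = df.sort_values("vertex_index")
        if not np.array_equal(df["vertex_index"].to_numpy(), np.arange(len(df))):
            raise ValueError("label CSV must cover vertices 0..n-1 exactly once")
        return cls(df["label"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"vertex_index": np.arange(len(self.labels)),
                      "label": self.labels}).to_csv(path, index=False)


# -- summaries --------------------------------------------------------------

def region_summary(field: GrowthField, labels: RegionLabels,
                   directions: Iterable[str] = ("ap", "si", "ml", "total")
                   ) -> pd.DataFrame:
    """Mean/SD of per-vertex rates per region, instance and direction.

    Returns a tidy frame with columns region, direction, instance, mean, sd,
    count.  SD is the sample standard deviation over member vertices.
    """
    if len(labels) != field.n_vertices:
        raise ValueError(
            f"label count {len(labels)} != vertex count {field.n_vertices}"
        )
    rows = []
    for region in REGIONS:
        idx = labels.indices(region)
        if len(idx) == 0:
            continue
        for direction in directions:
            arr = field.component(direction)[idx]  # (members, K)
            for k, t in enumerate(field.times):
                vals = arr[:, k]
                rows.append({
                    "region": region, "direction": direction,
                    "instance": int(round(t)),
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    "count": len(idx),
                })
    return pd.DataFrame(rows)


def _moller_trumbore(origins, directions, tri):
    """Ray/triangle hit distances; (R,) min positive t per ray (inf if none)."""
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    out = np.full(len(origins), np.inf)
    eps = 1e-12
    for i, (o, d) in enumerate(zip(origins, directions)):
        p = np.cross(d, e2)
        det = np.einsum("ij,ij->i", e1, p)
        ok = np.abs(det) > eps
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        tv = o - v0
        u = np.einsum("ij,ij->i", tv, p) * inv
        q = np.cross(tv, e1)
        v = np.einsum("ij,j->i", q, d) * inv
        t = np.einsum("ij,ij->i", q, e2) * inv
        hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps) & (t > 1e-6)
        if hit.any():
            out[i] = t[hit].min()
    return out


def region_thickness(mesh: TriangleMesh, labels: RegionLabels, region: str,
                     cutoff: float = 30.0) -> dict:
    """Mean thickness of a region by inward normal ray casting.

    For each region vertex a ray is cast along the inward vertex normal; the
    thickness is the distance to the first intersection with the opposing
    surface, counted only when within ``cutoff`` mm.  Returns mean thickness,
    per-vertex distances and the hit fraction (a warning is raised below 50%).
    """
    idx = labels.indices(region)
    if len(idx) == 0:
        raise ValueError(f"region {region!r} has no vertices")
    normals = mesh.vertex_normals()[idx]
    origins = mesh.vertices[idx] - 1e-9 * normals
    tri = mesh.vertices[mesh.faces]
    t = _moller_trumbore(origins, -normals, tri)
    hits = np.isfinite(t) & (t <= cutoff)
    frac = float(hits.mean())
    if frac < 0.5:
        warnings.warn(
            f"region {region!r}: only {frac:.0%} of inward rays hit the "
            f"opposing surface within {cutoff} mm", stacklevel=2)
    mean = float(t[hits].mean()) if hits.any() else np.nan
    return {"mean": mean, "hit_fraction": frac, "distances": t,
            "vertex_indices": idx}


def condylar_width(landmarks: LandmarkSet, side: str = "R") -> float:
    """Mediolateral width of the condylar head: |Cd-lat - Cd-med| for one side."""
    lat, med = f"{side}_Cd-lat", f"{side}_Cd-med"
    return float(np.linalg.norm(landmarks[lat] - landmarks[med]))
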