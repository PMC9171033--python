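"""Triangle-mesh data model, file I/O, decimation, neighborhoods and edges.

Meshes are closed triangulated bone surfaces with coordinates in mm,
right-handed, no axis flipping on read.  Vertex indices are 0-based
internally everywhere; OBJ files (1-based on disk) are converted on
read/write.  Duplicate vertices are welded within ``WELD_TOL`` mm on read —
five orders of magnitude below the 0.4 mm CBCT voxel scale the meshes come
from, so welding never merges genuinely distinct surface points.
"""
from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from ._decimate import quadric_decimate
from .errors import MeshInvariantError, MeshParseError
from .rigid import RigidTransform

WELD_TOL = 1e-6  # mm

_FORMATS = ("ply", "stl", "obj")


@dataclass
class TriangleMesh:
    """A triangulated surface: ``vertices`` (n, 3) in mm, ``faces`` (m, 3) 0-based.

    ``instance_label`` identifies the measurement instance (e.g. ``"T1"``).
    """

    vertices: np.ndarray
    faces: np.ndarray
    instance_label: Optional[str] = None

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshInvariantError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshInvariantError("faces must be an (m, 3) array")
        if len(self.vertices) == 0:
            raise MeshInvariantError("mesh has no vertices")
        if not np.isfinite(self.vertices).all():
            raise MeshInvariantError("non-finite vertex coordinates")
        n = len(self.vertices)
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= n):
            raise MeshInvariantError(
                f"face index out of range [0, {n}): "
                f"min {self.faces.min()}, max {self.faces.max()}"
            )
        f = self.faces
        if len(f) and ((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2])
                       | (f[:, 0] == f[:, 2])).any():
            raise MeshInvariantError("degenerate face with a repeated vertex index")

    # -- basic properties ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def mean_edge_length(self) -> float:
        e = mesh_edges(self)
        d = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
        return float(d.mean())

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals (outward for consistently wound closed meshes)."""
        return np.asarray(self.to_trimesh().vertex_normals, float)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(),
                            self.instance_label)


@dataclass
class MeshSeries:
    """Time-ordered meshes of the same bone; ``times`` in months, strictly increasing."""

    meshes: Sequence[TriangleMesh]
    times: np.ndarray

    def __post_init__(self):
        self.meshes = list(self.meshes)
        self.times = np.asarray(self.times, float)
        if len(self.meshes) < 2:
            raise MeshInvariantError("a series needs at least 2 meshes")
        if len(self.times) != len(self.meshes):
            raise MeshInvariantError("times and meshes length mismatch")
        if not (np.diff(self.times) > 0).all():
            raise MeshInvariantError("instance times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.meshes)

    def __getitem__(self, i) -> TriangleMesh:
        return self.meshes[i]


# -- cleanup ----------------------------------------------------------------

def weld_vertices(vertices: np.ndarray, faces: np.ndarray, tol: float = WELD_TOL):
    """Merge vertices closer than ``tol`` (grid snap), keeping first occurrences."""
    key = np.round(np.asarray(vertices, float) / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True,
                                  return_inverse=True)
    # preserve original ordering of first occurrences
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return vertices[first[order]], rank[inverse][faces]


def clean_mesh(vertices: np.ndarray, faces: np.ndarray,
               label: Optional[str] = None, tol: float = WELD_TOL) -> TriangleMesh:
    """Weld duplicates, drop degenerate faces and unreferenced vertices."""
    if len(vertices) == 0:
        raise MeshParseError("empty mesh (no vertices)")
    v, f = weld_vertices(np.asarray(vertices, float),
                         np.asarray(faces, np.int64), tol)
    if len(f):
        good = (f[:, 0] != f[:, 1]) & (f[:, 1] != f[:, 2]) & (f[:, 0] != f[:, 2])
        f = f[good]
    if len(f) == 0:
        raise MeshParseError("mesh has no valid (non-degenerate) faces")
    used = np.zeros(len(v), bool)
    used[f] = True
    remap = -np.ones(len(v), np.int64)
    remap[used] = np.arange(used.sum())
    return TriangleMesh(v[used], remap[f], label)


# -- reading ----------------------------------------------------------------

def _parse_obj(text: str) -> tuple[np.ndarray, np.ndarray]:
    verts, faces = [], []
    for ln, line in enumerate(text.splitlines(), start=1):
        parts = line.split()
        if not parts or parts[0].startswith("#"):
            continue
        if parts[0] == "v":
            if len(parts) < 4:
                raise MeshParseError(f"OBJ line {ln}: vertex needs 3 coordinates")
            try:
                verts.append([float(x) for x in parts[1:4]])
            except ValueError as e:
                raise MeshParseError(f"OBJ line {ln}: bad coordinate ({e})") from e
        elif parts[0] == "f":
            idx = []
            for tok in parts[1:]:
                head = tok.split("/")[0]
                try:
                    i = int(head)
                except ValueError as e:
                    raise MeshParseError(f"OBJ line {ln}: bad face index {head!r}") from e
                if i == 0:
                    raise MeshParseError(
                        f"OBJ line {ln}: face index 0 (OBJ indices are 1-based)"
                    )
                idx.append(i - 1 if i > 0 else len(verts) + i)
            if len(idx) < 3:
                raise MeshParseError(f"OBJ line {ln}: face needs >= 3 vertices")
            for k in range(1, len(idx) - 1):  # fan-triangulate polygons
                faces.append([idx[0], idx[k], idx[k + 1]])
    if not verts:
        raise MeshParseError("OBJ file contains no vertices")
    return np.asarray(verts, float), np.asarray(faces, np.int64).reshape(-1, 3)


def read_mesh(path, fmt: Optional[str] = None,
              instance_label: Optional[str] = None) -> TriangleMesh:
    """Read a PLY / STL / OBJ surface mesh and return a cleaned TriangleMesh.

    Cleanup welds duplicated vertex records within 1e-6 mm (STL stores every
    corner per facet) and drops unreferenced vertices and degenerate faces.
    """
    import trimesh

    path = Path(path)
    if not path.exists():
        raise MeshParseError(f"file not found: {path}")
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in _FORMATS:
        raise MeshParseError(f"unsupported format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "obj":
        v, f = _parse_obj(path.read_text())
        return clean_mesh(v, f, instance_label or path.stem)
    try:
        m = trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    except Exception as e:  # pragma: no cover - message path
        raise MeshParseError(f"cannot parse {fmt} file {path}: {e}") from e
    v = np.asarray(m.vertices, float)
    f = np.asarray(m.faces, np.int64)
    if v.size == 0:
        raise MeshParseError(f"empty mesh in {path}")
    return clean_mesh(v, f, instance_label or path.stem)


def read_vertex_scalars(path) -> Optional[np.ndarray]:
    """Return the per-vertex ``quality`` channel of a PLY file, if present."""
    import trimesh

    m = trimesh.load(str(path), file_type="ply", process=False, force="mesh")
    raw = m.metadata.get("_ply_raw", {})
    vert = raw.get("vertex", {})
    data = vert.get("data", {})
    if isinstance(data, dict) and "quality" in data:
        return np.asarray(data["quality"], float).ravel()
    if hasattr(data, "dtype") and "quality" in (data.dtype.names or ()):
        return np.asarray(data["quality"], float).ravel()
    return None


def read_vertex_colors(path) -> Optional[np.ndarray]:
    """Return (n, 3) uint8 vertex colors from a PLY file, if present."""
    import trimesh

    m = trimesh.load(str(path), file_type="ply", process=False, force="mesh")
    try:
        colors = np.asarray(m.visual.vertex_colors)
    except Exception:
        return None
    if colors is None or colors.size == 0:
        return None
    return colors[:, :3].astype(np.uint8)


# -- writing ----------------------------------------------------------------

def _fmt_row(row) -> str:
    return " ".join(format(x, ".10g") for x in row)


def write_mesh(mesh: TriangleMesh, path, fmt: Optional[str] = None,
               per_vertex_scalars: Optional[np.ndarray] = None,
               per_vertex_colors: Optional[np.ndarray] = None) -> Path:
    """Write a mesh as ASCII PLY / STL / OBJ with full double precision.

    Per-vertex scalars become the PLY ``property float quality`` channel;
    colors become ``uchar red/green/blue``.  Only PLY carries attributes.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported format {fmt!r}")
    n = mesh.n_vertices
    scalars = colors = None
    if per_vertex_scalars is not None:
        scalars = np.asarray(per_vertex_scalars, float).ravel()
        if len(scalars) != n:
            raise ValueError(f"scalar length {len(scalars)} != vertex count {n}")
    if per_vertex_colors is not None:
        colors = np.asarray(per_vertex_colors)
        if colors.shape != (n, 3):
            raise ValueError(f"colors must be (n, 3), got {colors.shape}")
        if colors.min() < 0 or colors.max() > 255:
            raise ValueError("color components must lie in [0, 255]")
        colors = colors.astype(np.uint8)
    if fmt != "ply" and (scalars is not None or colors is not None):
        raise ValueError("per-vertex scalars/colors are only supported for PLY")

    buf = _io.StringIO()
    V, F = mesh.vertices, mesh.faces
    if fmt == "ply":
        buf.write("ply\nformat ascii 1.0\ncomment produced by osteomap\n")
        buf.write(f"element vertex {n}\n")
        buf.write("property double x\nproperty double y\nproperty double z\n")
        if scalars is not None:
            buf.write("property float quality\n")
        if colors is not None:
            buf.write("property uchar red\nproperty uchar green\nproperty uchar blue\n")
        buf.write(f"element face {mesh.n_faces}\n")
        buf.write("property list uchar int vertex_indices\nend_header\n")
        for i in range(n):
            parts = [_fmt_row(V[i])]
            if scalars is not None:
                parts.append(format(scalars[i], ".9g"))
            if colors is not None:
                parts.append(" ".join(str(int(c)) for c in colors[i]))
            buf.write(" ".join(parts) + "\n")
        for f in F:
            buf.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    elif fmt == "obj":
        buf.write("# produced by osteomap\n")
        for v in V:
            buf.write("v " + _fmt_row(v) + "\n")
        for f in F:
            buf.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
    else:  # ascii STL
        name = mesh.instance_label or "osteomap"
        buf.write(f"solid {name}\n")
        for f in F:
            a, b, c = V[f[0]], V[f[1]], V[f[2]]
            nvec = np.cross(b - a, c - a)
            norm = np.linalg.norm(nvec)
            nvec = nvec / norm if norm > 0 else nvec
            buf.write(f"  facet normal {_fmt_row(nvec)}\n    outer loop\n")
            for p in (a, b, c):
                buf.write(f"      vertex {_fmt_row(p)}\n")
            buf.write("    endloop\n  endfacet\n")
        buf.write(f"endsolid {name}\n")
    path.write_text(buf.getvalue())
    return path


# -- operations -------------------------------------------------------------

def mesh_edges(mesh: TriangleMesh) -> np.ndarray:
    """Unique undirected edges from face adjacency, as an (E, 2) array with a < b."""
    f = mesh.faces
    e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    e.sort(axis=1)
    return np.unique(e, axis=0)


def vertex_neighborhood(mesh: TriangleMesh, j: int, r: float,
                        metric: str = "euclidean") -> np.ndarray:
    """Indices of vertices within distance ``r`` of vertex ``j`` (including ``j``).

    The default metric is the Euclidean ball; ``metric="geodesic"`` measures
    shortest paths along mesh edges instead (slower, but respects the surface
    on thin or folded geometry).
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    if not 0 <= j < mesh.n_vertices:
        raise IndexError(f"vertex {j} out of range")
    if metric == "euclidean":
        tree = cKDTree(mesh.vertices)
        idx = tree.query_ball_point(mesh.vertices[j], r)
        return np.array(sorted(idx), np.int64)
    if metric == "geodesic":
        e = mesh_edges(mesh)
        w = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
        n = mesh.n_vertices
        g = csr_matrix((np.r_[w, w], (np.r_[e[:, 0], e[:, 1]],
                                      np.r_[e[:, 1], e[:, 0]])), shape=(n, n))
        dist = dijkstra(g, indices=j, limit=r)
        return np.flatnonzero(np.isfinite(dist)).astype(np.int64)
    raise ValueError(f"unknown metric {metric!r}")


def apply_transform(mesh: TriangleMesh, transform: RigidTransform) -> TriangleMesh:
    """Map every vertex by ``R p + t``; rigidity preserves all pairwise distances."""
    return TriangleMesh(transform.apply(mesh.vertices), mesh.faces.copy(),
                        mesh.instance_label)


def decimate(mesh: TriangleMesh, target_n: int) -> TriangleMesh:
    """Quadric-error simplification to exactly ``target_n`` vertices.

    Watertightness of closed inputs is preserved (collapses violating the
    manifold link condition or flipping normals are rejected).
    """
    if target_n > mesh.n_vertices:
        raise ValueError(
            f"target_n {target_n} exceeds vertex count {mesh.n_vertices}"
        )
    if target_n == mesh.n_vertices:
        return mesh.copy()
    v, f = quadric_decimate(mesh.vertices, mesh.faces, target_n)
    return TriangleMesh(v, f, mesh.instance_label)
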