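"""Triangle-mesh container, Wavefront OBJ I/O and elementary mesh geometry.

All lengths are in meters (the native unit of structured-light scanners);
conversion to centimeters happens only when measurements are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

#: triangles smaller than this (m^2) are treated as degenerate but kept so
#: that face indices stay stable for the face-index buffer
DEGENERATE_AREA = 1e-14


class MeshError(ValueError):
    """Raised for malformed or inconsistent mesh data."""


@dataclass
class TriangleMesh:
    """Triangulated surface: ``vertices`` (n, 3) float meters, ``faces`` (m, 3) int.

    Faces are stored 0-based and are expected counter-clockwise when viewed
    from outside/above the skin surface, so face normals point "up" out of
    the skin.
    """

    vertices: np.ndarray
    faces: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=np.int64))

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(self.vertices)):
            raise MeshError("mesh vertices contain non-finite coordinates")
        if len(self.faces):
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise MeshError(
                    f"face index out of range: valid [0, {len(self.vertices) - 1}], "
                    f"got [{self.faces.min()}, {self.faces.max()}]"
                )
            f = self.faces
            if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
                raise MeshError("mesh contains faces with repeated vertices")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self, face_ids=None) -> np.ndarray:
        """Return (m, 3, 3) vertex coordinates per face."""
        f = self.faces if face_ids is None else self.faces[np.asarray(face_ids, dtype=np.int64)]
        return self.vertices[f]

    def face_normals(self) -> np.ndarray:
        """Unit face normals; zero vector for degenerate faces."""
        t = self.triangles()
        n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        return np.divide(n, norm, out=np.zeros_like(n), where=norm > 0)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals (unit; zero for isolated vertices)."""
        t = self.triangles()
        fn = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])  # area-weighted
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        return np.divide(vn, norm, out=np.zeros_like(vn), where=norm > 0)

    def boundary_edge_count(self) -> int:
        """Number of edges used by exactly one face (0 for a closed surface)."""
        if not len(self.faces):
            return 0
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e.sort(axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return int(np.sum(counts == 1))


def read_obj(path: str | Path) -> TriangleMesh:
    """Read an ASCII Wavefront OBJ file into a :class:`TriangleMesh`.

    Accepts ``v``, ``f``, ``vt``, ``vn`` records; ``f`` entries may use the
    ``v/vt/vn`` slash forms (texture/normal references are ignored) and
    negative (relative) indices.  Polygons with more than three vertices are
    fan-triangulated as (0,1,2), (0,2,3), ...  Indices are converted from
    OBJ's 1-based convention to 0-based.
    """
    path = Path(path)
    vertices: list[list[float]] = []
    faces: list[list[int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            kind = tokens[0]
            if kind == "v":
                if len(tokens) < 4:
                    raise MeshError(f"{path}:{lineno}: vertex record needs 3 coordinates: {raw!r}")
                try:
                    vertices.append([float(t) for t in tokens[1:4]])
                except ValueError as exc:
                    raise MeshError(f"{path}:{lineno}: bad vertex coordinate: {raw!r}") from exc
            elif kind == "f":
                if len(tokens) < 4:
                    raise MeshError(f"{path}:{lineno}: face record needs >= 3 indices: {raw!r}")
                idx = []
                for tok in tokens[1:]:
                    head = tok.split("/", 1)[0]
                    try:
                        i = int(head)
                    except ValueError as exc:
                        raise MeshError(f"{path}:{lineno}: bad face index {tok!r}") from exc
                    if i == 0:
                        raise MeshError(f"{path}:{lineno}: OBJ face indices are 1-based, got 0")
                    idx.append(i - 1 if i > 0 else len(vertices) + i)
                for k in range(1, len(idx) - 1):  # fan triangulation
                    faces.append([idx[0], idx[k], idx[k + 1]])
            # vt, vn, materials, groups, smoothing: ignored
    mesh = TriangleMesh(np.asarray(vertices, dtype=np.float64).reshape(-1, 3), np.asarray(faces, dtype=np.int64).reshape(-1, 3))
    return mesh


def write_obj(mesh: TriangleMesh, path: str | Path) -> None:
    """Write a mesh as ASCII OBJ (1-based indices, full float precision)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# woundmetrics triangle mesh\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def triangle_area(p0, p1, p2) -> float:
    """Area of the 3D triangle (p0, p1, p2) in m^2; 0 for degenerate input."""
    p0, p1, p2 = (np.asarray(p, dtype=np.float64) for p in (p0, p1, p2))
    return float(0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0)))


def triangle_areas(mesh: TriangleMesh, face_ids=None) -> np.ndarray:
    """Vectorized per-face areas (m^2)."""
    t = mesh.triangles(face_ids)
    return 0.5 * np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)


def signed_tetra_volume(origin, p0, p1, p2) -> float:
    """Signed volume of the tetrahedron (origin, p0, p1, p2) in m^3.

    Positive when (p0, p1, p2) is counter-clockwise seen from outside the
    tetrahedron (normal pointing away from the origin); swapping two face
    vertices flips the sign.
    """
    o, p0, p1, p2 = (np.asarray(p, dtype=np.float64) for p in (origin, p0, p1, p2))
    return float(np.dot(p0 - o, np.cross(p1 - o, p2 - o)) / 6.0)


def closed_mesh_volume(mesh: TriangleMesh, origin=(0.0, 0.0, 0.0)) -> float:
    """Volume enclosed by a closed, consistently oriented mesh (m^3).

    Sums signed tetrahedra from ``origin`` to every face and returns the
    absolute value.  For a closed oriented surface the result is independent
    of the origin; if the mesh has boundary edges a warning is logged and the
    result depends on the origin.
    """
    nb = mesh.boundary_edge_count()
    if nb:
        log.warning("closed_mesh_volume: mesh has %d boundary edges; result is origin-dependent", nb)
    o = np.asarray(origin, dtype=np.float64)
    t = mesh.triangles() - o
    vols = np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])) / 6.0
    return float(abs(vols.sum()))


def rotation_aligning_normal(n) -> np.ndarray:
    """Proper rotation R with R @ n = (0, 0, 1) for a unit vector n.

    Uses the Rodrigues rotation about axis n x z; the antipodal case
    n = (0, 0, -1) falls back to a half-turn about the x axis.
    """
    n = np.asarray(n, dtype=np.float64)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("cannot align a zero normal vector")
    n = n / norm
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(n, z))
    if c > 1.0 - 1e-15:
        return np.eye(3)
    if c < -1.0 + 1e-15:
        return np.diag([1.0, -1.0, -1.0])  # half turn about x
    axis = np.cross(n, z)
    s = np.linalg.norm(axis)
    axis = axis / s
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def apply_rotation(mesh: TriangleMesh, R) -> TriangleMesh:
    """Rigidly rotate a mesh about the world origin (isometry; faces unchanged)."""
    R = np.asarray(R, dtype=np.float64)
    return TriangleMesh(mesh.vertices @ R.T, mesh.faces.copy())
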