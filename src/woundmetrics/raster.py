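"""Software rasterizer producing the top-view image and the per-pixel,
depth-ordered face-index buffer.

The face-index buffer is the 2D <-> 3D bridge of the pipeline: for every
pixel of the top-view render it records the ``faces_per_pixel`` nearest mesh
faces whose projection covers the pixel center, nearest first.  Keeping
several depth layers (default 5) is what lets a deep wound's interior faces
be recovered even where they are occluded in the top-view image itself.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .camera import CameraSpec, project_points, world_to_screen_matrix
from .mesh import TriangleMesh

log = logging.getLogger(__name__)

SENTINEL = -1  # "no face" marker in the face-index buffer


@dataclass
class FaceIndexBuffer:
    """Per-pixel depth layers: ``face_ids`` and ``depths`` are
    (image_size, image_size, faces_per_pixel) arrays, nearest hit first;
    sentinel entries (face ``-1`` / depth ``inf``) are trailing."""

    face_ids: np.ndarray
    depths: np.ndarray
    spec: CameraSpec

    @property
    def image_size(self) -> int:
        return self.face_ids.shape[0]

    @property
    def faces_per_pixel(self) -> int:
        return self.face_ids.shape[2]

    def hit_set(self) -> set[tuple[int, int, int]]:
        """All (row, col, face_id) hits, for coverage comparisons."""
        rr, cc, _ = np.nonzero(self.face_ids != SENTINEL)
        ff = self.face_ids[self.face_ids != SENTINEL]
        return set(zip(rr.tolist(), cc.tolist(), ff.tolist()))

    def faces_under(self, pixel_mask: np.ndarray, layers: int | None = None) -> np.ndarray:
        """Unique face ids appearing in any of the first ``layers`` depth
        layers (default: all) under the True pixels of ``pixel_mask``."""
        layers = self.faces_per_pixel if layers is None else layers
        ids = self.face_ids[pixel_mask, :layers]
        ids = ids[ids != SENTINEL]
        return np.unique(ids)

    def save(self, path) -> None:
        """Serialize as a compressed .npz with a JSON header entry."""
        header = json.dumps(
            {
                "shape": list(self.face_ids.shape),
                "sentinel": SENTINEL,
                "camera": self.spec.__dict__,
            }
        )
        np.savez_compressed(path, face_ids=self.face_ids, depths=self.depths,
                            header=np.frombuffer(header.encode(), dtype=np.uint8))

    @classmethod
    def load(cls, path) -> "FaceIndexBuffer":
        data = np.load(path)
        header = json.loads(bytes(data["header"]).decode())
        return cls(data["face_ids"], data["depths"], CameraSpec(**header["camera"]))


@dataclass
class RenderResult:
    """Top-view render: shaded image, face-index buffer and the 4x4
    world->screen transform that produced them."""

    image: np.ndarray
    buffer: FaceIndexBuffer
    world_to_screen: np.ndarray
    centroid_shift: np.ndarray  # world translation applied before rendering


def _edge(ax, ay, bx, by, px, py):
    """Signed twice-area of (a, b, p); positive when p is left of a->b."""
    return (bx - ax) * (py - ay) - (by - ay) * (px - ax)


def _top_left(ax, ay, bx, by) -> bool:
    """Top-left fill rule for edge a->b in a y-down, CCW-normalized triangle."""
    return (ay == by and bx < ax) or (by < ay)


def rasterize(
    mesh: TriangleMesh,
    spec: CameraSpec | None = None,
    faces_per_pixel: int = 5,
    center: bool = True,
) -> RenderResult:
    """Render the mesh from ``spec``'s viewpoint.

    A face covers a pixel iff the pixel center lies inside its projected
    triangle (ties on shared edges broken by a top-left fill rule); per pixel
    the nearest ``faces_per_pixel`` covering faces are kept, sorted by
    perspective-correct camera-space depth.  When ``center`` is True the mesh
    centroid is first translated to the world origin so the camera distance
    is measured to the wound, mirroring the acquisition protocol.
    """
    if spec is None:
        spec = CameraSpec()
    if faces_per_pixel < 1:
        raise ValueError("faces_per_pixel must be >= 1")
    if mesh.n_faces == 0:
        raise ValueError("cannot rasterize an empty mesh")

    shift = mesh.vertices.mean(axis=0) if center else np.zeros(3)
    verts = mesh.vertices - shift

    pix, depth, in_front = project_points(verts, spec)
    S = spec.image_size
    K = faces_per_pixel

    tri = mesh.faces
    tri_front = in_front[tri].all(axis=1)
    n_skipped = int((~tri_front).sum())
    if n_skipped:
        log.warning("rasterize: %d faces have vertices behind the near plane; skipped", n_skipped)

    hits_pix: list[np.ndarray] = []
    hits_face: list[np.ndarray] = []
    hits_depth: list[np.ndarray] = []

    px, py = pix[:, 0], pix[:, 1]
    inv_z = 1.0 / depth
    for fid in np.nonzero(tri_front)[0]:
        i0, i1, i2 = tri[fid]
        x0, y0, x1, y1, x2, y2 = px[i0], py[i0], px[i1], py[i1], px[i2], py[i2]
        xmin = max(int(np.floor(min(x0, x1, x2) - 0.5)), 0)
        xmax = min(int(np.ceil(max(x0, x1, x2) - 0.5)), S - 1)
        ymin = max(int(np.floor(min(y0, y1, y2) - 0.5)), 0)
        ymax = min(int(np.ceil(max(y0, y1, y2) - 0.5)), S - 1)
        if xmin > xmax or ymin > ymax:
            continue
        area2 = _edge(x0, y0, x1, y1, x2, y2)
        if area2 == 0.0:
            continue  # edge-on or degenerate projection
        cols = np.arange(xmin, xmax + 1)
        rows = np.arange(ymin, ymax + 1)
        cx = cols[None, :] + 0.5
        cy = rows[:, None] + 0.5
        w0 = _edge(x1, y1, x2, y2, cx, cy)
        w1 = _edge(x2, y2, x0, y0, cx, cy)
        w2 = _edge(x0, y0, x1, y1, cx, cy)
        if area2 < 0.0:
            w0, w1, w2, a2 = -w0, -w1, -w2, -area2
        else:
            a2 = area2
        inside = (
            (w0 > 0) | ((w0 == 0) & _top_left(x1, y1, x2, y2))
        ) & (
            (w1 > 0) | ((w1 == 0) & _top_left(x2, y2, x0, y0))
        ) & (
            (w2 > 0) | ((w2 == 0) & _top_left(x0, y0, x1, y1))
        )
        if not inside.any():
            continue
        rr, cc = np.nonzero(inside)
        l0 = w0[inside] / a2
        l1 = w1[inside] / a2
        l2 = w2[inside] / a2
        # perspective-correct depth: 1/z interpolates linearly in screen space
        z = 1.0 / (l0 * inv_z[i0] + l1 * inv_z[i1] + l2 * inv_z[i2])
        hits_pix.append((rows[rr] * S + cols[cc]).astype(np.int64))
        hits_face.append(np.full(len(rr), fid, dtype=np.int64))
        hits_depth.append(z)

    face_ids = np.full((S * S, K), SENTINEL, dtype=np.int64)
    depths = np.full((S * S, K), np.inf)

    if hits_pix:
        hp = np.concatenate(hits_pix)
        hf = np.concatenate(hits_face)
        hd = np.concatenate(hits_depth)
        order = np.lexsort((hf, hd, hp))  # by pixel, then depth (face id breaks ties)
        hp, hf, hd = hp[order], hf[order], hd[order]
        # layer index = rank within its pixel run
        first = np.r_[True, hp[1:] != hp[:-1]]
        run_start = np.maximum.accumulate(np.where(first, np.arange(len(hp)), 0))
        layer = np.arange(len(hp)) - run_start
        keep = layer < K
        face_ids[hp[keep], layer[keep]] = hf[keep]
        depths[hp[keep], layer[keep]] = hd[keep]
    else:
        warnings.warn("rasterize: mesh projects entirely outside the image frustum")

    face_ids = face_ids.reshape(S, S, K)
    depths = depths.reshape(S, S, K)

    buffer = FaceIndexBuffer(face_ids, depths, replace(spec))
    image = _shade(mesh, buffer, spec)
    return RenderResult(image, buffer, world_to_screen_matrix(spec), shift)


def _shade(mesh: TriangleMesh, buffer: FaceIndexBuffer, spec: CameraSpec) -> np.ndarray:
    """Simple Lambertian head-light shading of the nearest layer (for
    visualization only; measurement never reads the image)."""
    normals = mesh.face_normals()
    f0 = buffer.face_ids[:, :, 0]
    view = spec.position / np.linalg.norm(spec.position)
    lam = np.abs(normals @ view)
    img = np.zeros(f0.shape)
    hit = f0 != SENTINEL
    img[hit] = 0.15 + 0.85 * lam[f0[hit]]
    return img
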