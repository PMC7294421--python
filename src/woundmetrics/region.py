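"""Wound region extraction: warped top-view mask + face-index buffer ->
sets of mesh faces and vertices for the wound interior and boundary.

All depth layers of the buffer are used, so faces of a deep wound occluded
in the top-view image are still assigned to the region.  A face touching
both boundary and interior pixels is classed as boundary ("boundary
precedence"): the boundary ring feeds the rim-plane fit, and erring toward
more rim support stabilizes RANSAC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .matching import mask_boundary
from .mesh import TriangleMesh
from .raster import FaceIndexBuffer


class EmptyRegionError(ValueError):
    """The mask does not intersect the rendered mesh footprint."""


@dataclass
class WoundRegion:
    """Face/vertex id sets for the wound on the mesh.  ``interior_faces``
    and ``boundary_faces`` are disjoint; vertex sets follow the same
    boundary-precedence rule."""

    interior_faces: np.ndarray
    boundary_faces: np.ndarray
    interior_vertices: np.ndarray = field(default=None)  # type: ignore[assignment]
    boundary_vertices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.interior_faces = np.unique(np.asarray(self.interior_faces, dtype=np.int64))
        self.boundary_faces = np.unique(np.asarray(self.boundary_faces, dtype=np.int64))
        if np.intersect1d(self.interior_faces, self.boundary_faces).size:
            raise ValueError("interior and boundary face sets overlap")
        for name in ("interior_vertices", "boundary_vertices"):
            v = getattr(self, name)
            setattr(self, name, np.unique(np.asarray(v, dtype=np.int64)) if v is not None
                    else np.zeros(0, dtype=np.int64))

    @classmethod
    def from_faces(cls, mesh: TriangleMesh, interior_faces, boundary_faces) -> "WoundRegion":
        """Build a region from face id sets, deriving vertex sets with
        boundary precedence."""
        interior_faces = np.unique(np.asarray(interior_faces, dtype=np.int64))
        boundary_faces = np.unique(np.asarray(boundary_faces, dtype=np.int64))
        interior_faces = np.setdiff1d(interior_faces, boundary_faces)
        bv = np.unique(mesh.faces[boundary_faces]) if boundary_faces.size else np.zeros(0, np.int64)
        iv = np.unique(mesh.faces[interior_faces]) if interior_faces.size else np.zeros(0, np.int64)
        iv = np.setdiff1d(iv, bv)
        return cls(interior_faces, boundary_faces, iv, bv)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "interior_faces": self.interior_faces.tolist(),
                "boundary_faces": self.boundary_faces.tolist(),
                "interior_vertices": self.interior_vertices.tolist(),
                "boundary_vertices": self.boundary_vertices.tolist(),
            }
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "WoundRegion":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(d["interior_faces"], d["boundary_faces"],
                   d["interior_vertices"], d["boundary_vertices"])


def region_from_mask(
    mask: np.ndarray, buffer: FaceIndexBuffer, mesh: TriangleMesh
) -> WoundRegion:
    """Map wound mask pixels to mesh faces via the face-index buffer.

    Boundary faces are all (any-layer) faces under the mask's one-pixel
    boundary ring; interior faces are all faces under interior pixels, minus
    the boundary set.  Raises :class:`EmptyRegionError` when the mask misses
    the rendered mesh entirely.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (buffer.image_size, buffer.image_size):
        raise ValueError(
            f"mask shape {mask.shape} does not match buffer image size {buffer.image_size}"
        )
    if not mask.any():
        raise EmptyRegionError("wound mask is empty")
    bnd_px = mask_boundary(mask)
    int_px = mask & ~bnd_px
    boundary_faces = buffer.faces_under(bnd_px)
    interior_faces = np.setdiff1d(buffer.faces_under(int_px), boundary_faces)
    if boundary_faces.size == 0 and interior_faces.size == 0:
        raise EmptyRegionError("wound mask does not overlap the rendered mesh footprint")
    return WoundRegion.from_faces(mesh, interior_faces, boundary_faces)


def region_vertices_3d(
    region: WoundRegion, mesh: TriangleMesh
) -> tuple[np.ndarray, np.ndarray]:
    """World-space coordinates of (boundary points, interior points)."""
    return mesh.vertices[region.boundary_vertices], mesh.vertices[region.interior_vertices]
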