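"""Photograph -> top-view registration: projective-transform fitting from
point correspondences, mask warping, and mask morphology.

The wound photograph and the rendered top view see a near-planar scene, so a
3x3 homography fitted from >= 4 matched landmarks transfers the photograph's
segmentation mask into top-view pixel space, where the face-index buffer
turns pixels into mesh faces.  Landmark matching itself is an input artifact
here: correspondences come from a file.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import measure as _sk_measure
from skimage import morphology as _sk_morph

import imageio.v3 as iio


class DegenerateCorrespondencesError(ValueError):
    """Raised when the correspondence configuration cannot determine a homography."""


@dataclass
class PointCorrespondences:
    """Paired landmarks: ``photo`` and ``topview`` are (n, 2) pixel
    coordinates (x=column, y=row), n >= 4."""

    photo: np.ndarray
    topview: np.ndarray

    def __post_init__(self) -> None:
        self.photo = np.asarray(self.photo, dtype=np.float64).reshape(-1, 2)
        self.topview = np.asarray(self.topview, dtype=np.float64).reshape(-1, 2)
        if len(self.photo) != len(self.topview):
            raise ValueError("photo and top-view point lists differ in length")
        if len(self.photo) < 4:
            raise ValueError(f"need >= 4 correspondences, got {len(self.photo)}")
        uniq = np.unique(self.photo, axis=0)
        if len(uniq) < len(self.photo):
            raise ValueError("duplicated source (photo) points in correspondences")

    def __len__(self) -> int:
        return len(self.photo)


def load_correspondences(path: str | Path) -> PointCorrespondences:
    """Read correspondences from CSV (header ``x_photo,y_photo,x_topview,
    y_topview``) or from a JSON list of 4-element rows."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = np.asarray(json.loads(path.read_text()), dtype=np.float64)
    else:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"x_photo", "y_photo", "x_topview", "y_topview"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise ValueError(
                    f"{path}: correspondence CSV must have header columns {sorted(required)}"
                )
            rows = np.asarray(
                [
                    [float(r["x_photo"]), float(r["y_photo"]),
                     float(r["x_topview"]), float(r["y_topview"])]
                    for r in reader
                ]
            )
    return PointCorrespondences(rows[:, :2], rows[:, 2:])


def save_correspondences(corr: PointCorrespondences, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x_photo", "y_photo", "x_topview", "y_topview"])
        for (xp, yp), (xt, yt) in zip(corr.photo, corr.topview):
            writer.writerow([repr(float(xp)), repr(float(yp)), repr(float(xt)), repr(float(yt))])


def _hartley_normalization(pts: np.ndarray) -> np.ndarray:
    """Similarity transform moving points to centroid 0, mean radius sqrt(2)."""
    c = pts.mean(axis=0)
    scale = np.sqrt(2.0) / max(np.mean(np.linalg.norm(pts - c, axis=1)), 1e-300)
    return np.array([[scale, 0, -scale * c[0]], [0, scale, -scale * c[1]], [0, 0, 1]])


def _collinear_triple(pts: np.ndarray, tol: float) -> tuple[int, int, int] | None:
    from itertools import combinations

    for i, j, k in combinations(range(len(pts)), 3):
        a, b, c = pts[i], pts[j], pts[k]
        area2 = abs((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))
        span = max(np.linalg.norm(b - a), np.linalg.norm(c - a), 1e-300)
        if area2 / span**2 < tol:
            return (i, j, k)
    return None


def fit_projective(corr: PointCorrespondences) -> tuple[np.ndarray, np.ndarray]:
    """Fit the 3x3 homography mapping photo pixels to top-view pixels.

    Normalized direct linear transform: both point sets are Hartley-
    normalized, the 2n x 9 design matrix is solved by SVD (smallest singular
    vector), and the result is denormalized and scaled so H[2,2] = 1.  For
    n = 4 this interpolates exactly; for n > 4 it is the least-squares
    solution in the normalized algebraic sense.

    Returns ``(H, residuals)`` with per-point Euclidean reprojection
    residuals in top-view pixels.
    """
    src, dst = corr.photo, corr.topview
    if len(src) == 4:
        tri = _collinear_triple(src, 1e-9) or _collinear_triple(dst, 1e-9)
        if tri is not None:
            raise DegenerateCorrespondencesError(
                f"correspondences {tri} are collinear; homography is underdetermined"
            )
    T_src = _hartley_normalization(src)
    T_dst = _hartley_normalization(dst)
    s = (np.column_stack([src, np.ones(len(src))]) @ T_src.T)
    d = (np.column_stack([dst, np.ones(len(dst))]) @ T_dst.T)

    A = np.zeros((2 * len(src), 9))
    A[0::2, 0:3] = s
    A[0::2, 6:9] = -d[:, [0]] * s
    A[1::2, 3:6] = s
    A[1::2, 6:9] = -d[:, [1]] * s
    _, sv, Vt = np.linalg.svd(A)
    if sv[-2] < 1e-12 * max(sv[0], 1.0):
        raise DegenerateCorrespondencesError(
            "degenerate correspondence configuration (rank-deficient DLT system)"
        )
    Hn = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(T_dst) @ Hn @ T_src
    if abs(H[2, 2]) > 1e-12:
        H = H / H[2, 2]
    if abs(np.linalg.det(H)) < 1e-12:
        raise DegenerateCorrespondencesError("fitted homography is singular")
    residuals = np.linalg.norm(apply_homography(H, src) - dst, axis=1)
    return H, residuals


def apply_homography(H: np.ndarray, points) -> np.ndarray:
    """Apply a 3x3 homography to (n, 2) pixel points."""
    p = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    ph = np.column_stack([p, np.ones(len(p))]) @ np.asarray(H).T
    return ph[:, :2] / ph[:, [2]]


def warp_mask(mask: np.ndarray, H: np.ndarray, out_size: int | tuple[int, int]) -> np.ndarray:
    """Warp a binary mask through H (source-pixel -> output-pixel map).

    Inverse mapping with nearest-neighbor sampling keeps the mask binary:
    each output pixel center (half-integer convention) is pulled back through
    H^-1 and samples the nearest source pixel; pixels mapping outside the
    source image become False.
    """
    mask = np.asarray(mask, dtype=bool)
    if np.isscalar(out_size):
        out_shape = (int(out_size), int(out_size))
    else:
        out_shape = (int(out_size[0]), int(out_size[1]))
    H = np.asarray(H, dtype=np.float64)
    if abs(np.linalg.det(H)) < 1e-12:
        raise ValueError("cannot warp through a non-invertible homography")
    Hinv = np.linalg.inv(H)
    rows, cols = np.mgrid[0 : out_shape[0], 0 : out_shape[1]]
    centers = np.column_stack([cols.ravel() + 0.5, rows.ravel() + 0.5])
    src = apply_homography(Hinv, centers)
    sc = np.floor(src[:, 0]).astype(np.int64)  # center (j+0.5) falls in column j
    sr = np.floor(src[:, 1]).astype(np.int64)
    valid = (sr >= 0) & (sr < mask.shape[0]) & (sc >= 0) & (sc < mask.shape[1])
    out = np.zeros(out_shape[0] * out_shape[1], dtype=bool)
    out[valid] = mask[sr[valid], sc[valid]]
    return out.reshape(out_shape)


def dilate_mask(mask: np.ndarray, radius: int) -> np.ndarray:
    """Morphological dilation with a disk structuring element (radius 0 is
    the identity).  Used to slightly enlarge mask borders so the whole wound
    survives the transfer into top-view space."""
    if radius < 0:
        raise ValueError("dilation radius must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if radius == 0:
        return mask.copy()
    return _sk_morph.dilation(mask, _sk_morph.disk(radius)).astype(bool)


def erode_mask(mask: np.ndarray, radius: int) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if radius == 0:
        return mask.copy()
    return _sk_morph.erosion(mask, _sk_morph.disk(radius)).astype(bool)


def mask_boundary(mask: np.ndarray) -> np.ndarray:
    """One-pixel-thick inner boundary ring: mask AND NOT erode(mask, 1)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask_boundary of an empty mask")
    return mask & ~_sk_morph.erosion(mask, _sk_morph.disk(1)).astype(bool)


def load_mask(path: str | Path, largest_component: bool = True) -> np.ndarray:
    """Read a binary mask from PNG: any nonzero channel value is True.  By
    default only the largest connected component is kept (segmentation output
    can contain speckle)."""
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., :3].max(axis=2)
    mask = img > 0
    if largest_component and mask.any():
        labels = _sk_measure.label(mask)
        largest = np.argmax(np.bincount(labels[mask]))
        mask = labels == largest
    return mask


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))
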