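"""End-to-end pipeline: photo mask -> homography warp -> face extraction ->
measurement, plus configuration and report I/O.

Stages and their artifacts:

1. ``rasterize``   — top-view render + face-index buffer of the OBJ mesh;
2. ``matching``    — homography from correspondences, photo mask warped
                     into top-view space and slightly dilated;
3. ``extraction``  — mask pixels -> wound interior/boundary faces;
4. ``measurement`` — rim plane, depth, area, volume, axes (cm units).

The external segmentation stage is an interface: any tool producing a
binary PNG mask of the wound photograph can slot in.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .camera import CameraSpec
from .matching import (
    PointCorrespondences,
    dilate_mask,
    fit_projective,
    load_correspondences,
    load_mask,
    save_mask,
    warp_mask,
)
from .measure import MeasurementConfig, WoundMeasurements, measure_wound
from .mesh import TriangleMesh, read_obj
from .raster import RenderResult, rasterize
from .region import WoundRegion, region_from_mask

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

#: stable exit codes per failing pipeline stage (CLI contract)
STAGE_EXIT_CODES = {
    "input": 2,
    "rasterize": 3,
    "matching": 4,
    "extraction": 5,
    "measurement": 6,
}


class PipelineStageError(RuntimeError):
    """Failure in a named pipeline stage, with a remedy hint."""

    def __init__(self, stage: str, message: str, hint: str = ""):
        self.stage = stage
        self.hint = hint
        super().__init__(f"[{stage}] {message}" + (f" (hint: {hint})" if hint else ""))

    @property
    def exit_code(self) -> int:
        return STAGE_EXIT_CODES.get(self.stage, 1)


@dataclass
class PipelineConfig:
    """Full pipeline configuration; echoed verbatim into every report."""

    camera: CameraSpec = field(default_factory=CameraSpec)
    faces_per_pixel: int = 5
    mask_dilation_px: int = 2
    measurement: MeasurementConfig = field(default_factory=MeasurementConfig)

    def __post_init__(self) -> None:
        if self.faces_per_pixel < 1:
            raise ValueError("faces_per_pixel must be >= 1")
        if self.mask_dilation_px < 0:
            raise ValueError("mask_dilation_px must be >= 0")

    def to_dict(self) -> dict:
        return {
            "camera": dataclasses.asdict(self.camera),
            "faces_per_pixel": self.faces_per_pixel,
            "mask_dilation_px": self.mask_dilation_px,
            "measurement": dataclasses.asdict(self.measurement),
        }

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        camera = CameraSpec(**data.get("camera", {}))
        measurement = MeasurementConfig(**data.get("measurement", {}))
        top = {k: v for k, v in data.items() if k in ("faces_per_pixel", "mask_dilation_px")}
        return cls(camera=camera, measurement=measurement, **top)


@dataclass
class PipelineResult:
    measurements: WoundMeasurements
    region: WoundRegion
    render: RenderResult
    warped_mask: np.ndarray
    homography: np.ndarray
    report: dict


def run_pipeline(
    mesh: TriangleMesh | str | Path,
    photo_mask: np.ndarray | str | Path,
    correspondences: PointCorrespondences | str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full measurement pipeline.

    Inputs may be in-memory objects or file paths (OBJ mesh, PNG mask, CSV/
    JSON correspondences).  When ``out_dir`` is given, the report JSON, the
    warped mask and the top-view render are written there.
    """
    cfg = config or PipelineConfig()

    try:
        if not isinstance(mesh, TriangleMesh):
            mesh = read_obj(mesh)
        if not isinstance(photo_mask, np.ndarray):
            photo_mask = load_mask(photo_mask)
    except (OSError, ValueError) as exc:
        raise PipelineStageError("input", str(exc), "check input file paths and formats") from exc

    try:
        render = rasterize(mesh, cfg.camera, faces_per_pixel=cfg.faces_per_pixel)
    except ValueError as exc:
        raise PipelineStageError("rasterize", str(exc), "check mesh units and camera distance") from exc

    try:
        if not isinstance(correspondences, PointCorrespondences):
            correspondences = load_correspondences(correspondences)
        H, residuals = fit_projective(correspondences)
        warped = warp_mask(photo_mask, H, cfg.camera.image_size)
        warped = dilate_mask(warped, cfg.mask_dilation_px)
        if not warped.any():
            raise ValueError("warped mask is empty inside the top view")
    except (OSError, ValueError) as exc:
        raise PipelineStageError(
            "matching", str(exc), "verify correspondences map the photo onto the top view"
        ) from exc

    try:
        region = region_from_mask(warped, render.buffer, mesh)
    except ValueError as exc:
        raise PipelineStageError(
            "extraction", str(exc), "mask may not overlap the rendered mesh footprint"
        ) from exc

    try:
        measurements = measure_wound(mesh, region, cfg.measurement)
    except ValueError as exc:
        raise PipelineStageError("measurement", str(exc)) from exc

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "measurements": measurements.to_dict(),
        "homography": np.asarray(H).tolist(),
        "homography_max_residual_px": float(np.max(residuals)),
        "region": {
            "n_interior_faces": int(len(region.interior_faces)),
            "n_boundary_faces": int(len(region.boundary_faces)),
        },
        "config": cfg.to_dict(),
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
        save_mask(warped, out_dir / "warped_mask.png")
        _save_image(render.image, out_dir / "top_view.png")

    return PipelineResult(measurements, region, render, warped, np.asarray(H), report)


def _save_image(image: np.ndarray, path: Path) -> None:
    import imageio.v3 as iio

    img = np.clip(image, 0.0, 1.0)
    iio.imwrite(path, (img * 255).astype(np.uint8))
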