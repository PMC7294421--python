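"""End-to-end pipeline on a fabricated photograph of a synthetic wound.

The scene generator renders the wound's top view, derives the exact wound
mask, distorts it through a random homography into a synthetic "photograph"
mask, and emits landmark correspondences.  The pipeline then has to undo
all of that: fit the homography, warp the mask back, map mask pixels to
mesh faces through the face-index buffer, and measure the wound in 3D.
"""

from woundmetrics import (
    CameraSpec,
    PipelineConfig,
    SyntheticWoundSpec,
    dice,
    make_scene,
    make_wound,
    run_pipeline,
)

spec = SyntheticWoundSpec(shape="spherical_cap", sphere_radius=0.02, depth=0.01,
                          resolution=30, tilt_deg=25.0)
mesh, gt = make_wound(spec)
camera = CameraSpec(image_size=2048)  # 0.3 m top-down view, 60 deg fov
scene = make_scene(mesh, gt, camera=camera, seed=1)

config = PipelineConfig(camera=camera, mask_dilation_px=1)
result = run_pipeline(mesh, scene.photo_mask, scene.correspondences, config)

m = result.measurements
print(f"warped-mask Dice vs true top-view mask: "
      f"{dice(result.warped_mask, scene.topview_mask):.4f}")
print(f"homography max landmark residual: "
      f"{result.report['homography_max_residual_px']:.2e} px")
print(f"depth      {m.depth_cm:7.3f} cm    (truth {gt.depth * 100:.3f})")
print(f"area       {m.area_cm2:7.3f} cm^2  (truth {gt.area * 1e4:.3f})")
print(f"volume     {m.volume_cm3:7.3f} cm^3  (truth {gt.volume * 1e6:.3f})")
print(f"major axis {m.major_axis_cm:7.3f} cm    (truth {gt.major_axis * 100:.3f})")
print(f"minor axis {m.minor_axis_cm:7.3f} cm    (truth {gt.minor_axis * 100:.3f})")
print("\nThe Dice score shows the photograph mask survived the projective")
print("round trip; the measurements come solely from mesh faces recovered")
print("through the warped mask and the 5-layer face-index buffer.")
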