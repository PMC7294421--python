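"""Volume validity gating on convex and flat control wounds.

A wound volume is only meaningful when the wound floor lies below the plane
of its rim.  Wounds over bone (heel, hip) can bulge above that plane; the
tetrahedron sum then counts volume that is not wound, so the pipeline flags
it instead of reporting a number.
"""

from woundmetrics import SyntheticWoundSpec, make_wound, measure_wound

for shape in ("spherical_cap", "convex_bump", "flat_disk"):
    mesh, gt = make_wound(SyntheticWoundSpec(shape=shape, resolution=20))
    m = measure_wound(mesh, gt.region(mesh))
    vol = f"{m.volume_cm3:7.3f} cm^3" if m.volume_valid else "   -- flagged invalid --"
    print(f"{shape:<16} depth {m.depth_cm:6.3f} cm   volume {vol}")
    for w in m.warnings:
        print(f"    warning: {w}")

print("\nThe cap reports its volume; the bump (a wound pushed above its rim)")
print("is measured but its volume is withheld; the flat disk is a zero-depth")
print("limit case and correctly reports ~0 volume.")
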