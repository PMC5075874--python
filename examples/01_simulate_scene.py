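"""Render one synthetic chamber scene and inspect its ground truth.

The generator emulates a bright-field view of a micro-pillar chamber: dark
curved worms on a light background, one cluster of touching worms, and exact
per-worm ground truth (label image, midlines, areas).
"""

from wormchip import ClusterSpec, SceneSpec, render_scene

spec = SceneSpec(
    n_worms=8,
    cluster_plan=(ClusterSpec((0, 1, 2), "mixed"),),
    fluor_per_worm=(20, 30, 40, 10, 10, 10, 10, 10),
    seed=42,
)
brightfield, fluorescence, truth = render_scene(spec)

print(f"image: {brightfield.shape[0]} x {brightfield.shape[1]} px")
print(f"worms: {len(truth.worms)} (labels 1..{truth.label_image.max()})")
for w in truth.worms[:4]:
    member = f"cluster {w.cluster_id}" if w.cluster_id is not None else "isolated"
    print(
        f"  worm {w.worm_id}: area {w.area_px} px, "
        f"midline length {w.length_px:.0f} px, {member}"
    )
# The label image is the exact per-pixel answer key every analysis stage is
# scored against; areas around 1000 px correspond to a 100 x 10 px worm.
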