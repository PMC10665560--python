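"""Region-proposal anchor geometry and training-time augmentation.

Shows the anchor grid implied by the detector's generator settings (scale 8;
strides 4-64; aspect ratios 0.5, 1, 2 on a 512x512 image), the label
assignment rule for proposals, and the eight-orientation augmentation.
"""

import numpy as np

from spinetrack import (
    AnchorConfig,
    Box2D,
    anchor_count,
    assign_anchor_labels,
    augment,
    combine_losses,
    enumerate_orientations,
    generate_anchors,
)

cfg = AnchorConfig()
anchors = generate_anchors(cfg)
print(f"default 512x512 grid: {len(anchors):,} anchors "
      f"(closed form {anchor_count(cfg):,})")

gt = Box2D(100, 100, 132, 132)
labels = assign_anchor_labels(anchors[:0] + [gt.as_tuple(), (300.0, 300.0, 332.0, 332.0)], [gt])
print(f"exact-match anchor -> {labels[0]}, far anchor -> {labels[1]}")

img = np.arange(36, dtype=float).reshape(6, 6)
orientations = enumerate_orientations(img)
distinct = len({o.tobytes() for o in orientations})
print(f"orientations of a generic image: {len(orientations)} produced, {distinct} distinct")

out, boxes = augment(img * 7, [Box2D(1, 1, 4, 5)], np.random.default_rng(0))
print(f"augmented box area preserved: {boxes[0].area:.1f} (was 12.0)")

loss = combine_losses(1.0, 0.5, 0.8, 0.25, 1e6)
print(f"combined training loss (alpha=2, lambda=3e-6): {loss:.2f}")
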