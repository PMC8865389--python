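"""Generate one synthetic slide and walk it through slide preparation.

Builds a category-3 slide with several tissue blobs, segments the tissue
slices, marks the ROI-bearing one, and tiles each slice into the per-scale
patch grids the model consumes (25/49/81 patches at 7.5x/10x/12.5x).
"""

import numpy as np

from scaleformer import SynthConfig, generate_slide, prepare_slide, tile_patches
from scaleformer.slide_prep import DEFAULT_M_PER_SCALE

record, blobs = generate_slide(SynthConfig(), class_index=3,
                               rng=np.random.default_rng(7), slide_id="demo")
print(f"slide class: {record.class_name}; generated blobs: {len(blobs)}")
for b in blobs:
    print(f"  blob {b.blob_index}: class {b.class_index}, centroid {b.centroid},"
          f" roi={b.is_roi}")

slices = prepare_slide(record)
print(f"\nextracted {len(slices)} tissue slices (sorted by area):")
for sl in slices:
    grids = {tag: tile_patches(sl.crops[tag], m, tag).patches.shape
             for tag, m in DEFAULT_M_PER_SCALE.items()}
    print(f"  {sl.slice_id}: area {sl.area}, roi={sl.has_roi}")
    for tag, shape in sorted(grids.items()):
        print(f"     {tag}: {shape[0]} patches of {shape[1]}x{shape[2]}")
# Slice count should equal the generated blob count, and exactly one slice
# should carry the ROI flag.
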