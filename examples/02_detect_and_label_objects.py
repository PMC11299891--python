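"""Run the coarse detection stage on one B-scan and auto-label the objects.

Detection is threshold -> merging blur -> connected components -> area
filter.  On a labeled phantom, each detected object can be assigned its
ground-truth class by majority overlap with the label volume — the
automatic stand-in for a human audit.
"""

from octtm import (
    CI_LARGE_STAGE, PhantomConfig, auto_label_object, detect_objects,
    generate_phantom,
)

volume, labels = generate_phantom(PhantomConfig.ci(seed=11))
# pick the busiest slice: saturation lines weld everything they cross into
# one object, so slices they miss show the richest object mix
y = max(range(volume.n_slices),
        key=lambda i: len(detect_objects(volume.slice(i), CI_LARGE_STAGE, i)))
objects = detect_objects(volume.slice(y), CI_LARGE_STAGE, y)

print(f"slice {y}: {len(objects)} objects with the coarse parameters "
      f"(threshold {CI_LARGE_STAGE.threshold}, blur {CI_LARGE_STAGE.blur}, "
      f"min area {CI_LARGE_STAGE.min_area})")
for obj in objects:
    truth = auto_label_object(obj, labels)
    x, z, w, h = obj.bbox
    print(f"  area {obj.area:5d}  bbox x={x:3d} z={z:3d} {w:3d}x{h:3d}  -> {truth}")
# Objects labeled TM contain the membrane band (possibly with a merged
# nearby blob); non-TM objects are artifacts, deep structures, or membrane
# welded to a saturation line by the merging blur.
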