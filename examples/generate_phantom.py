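"""Generate a synthetic long-bone phantom and inspect its ground truth.

Builds a femur-like shaft whose medullary cavity is filled with rods
aligned to the long axis, then prints what the generator guarantees:
the achieved trabecular fill of the cavity, the true strut width, and
the label composition of the volume.
"""

import numpy as np

from osteofabric.phantom import femur_phantom_spec, make_long_bone

spec = femur_phantom_spec("aligned", seed=1)
vol, gt = make_long_bone(spec)

labels = gt.labels.labels
names = {0: "air", 1: "cortical", 2: "trabecular", 3: "cavity"}
print(f"grid {vol.shape} at {vol.spacing[0]:.0f} um voxels")
print(f"achieved cavity fill: {gt.true_fill:.3f} (requested 0.30 +/- 0.02)")
print(f"true strut width:     {gt.true_tb_th:.0f} um")
for value, name in names.items():
    frac = (labels == value).mean()
    print(f"  label {value} ({name:10s}): {frac:6.1%} of voxels")

rods = labels == 2
axes = gt.orientation_field[rods]
ang = np.degrees(np.arccos(np.clip(np.abs(axes[:, 2]), -1, 1)))
print(f"rod axes vs long axis: median {np.median(ang):.1f} deg "
      "(terrestrial-like fabric: struts track the long axis)")
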