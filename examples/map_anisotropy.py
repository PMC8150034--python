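"""Whole-bone trabecular anisotropy mapping, terrestrial vs aquatic fabric.

Runs the complete pipeline — filter chain, cortical/trabecular
segmentation, spherical-VOI lattice, surface-normal fabric tensors — on
two phantoms that differ only in rod orientation, and prints the
summary statistic the method rests on: the modal degree of anisotropy
(Ani.M) of the zero-excluded histogram.  Aligned struts (habitual
loading along the limb) push the mode high; disordered struts keep it
low.
"""

from osteofabric.fabric import coherence, filter_high
from osteofabric.phantom import femur_phantom_spec, make_long_bone
from osteofabric.pipeline import analyse_volume

for fabric, story in (("aligned", "terrestrial-like"), ("isotropic", "aquatic-like")):
    vol, _ = make_long_bone(femur_phantom_spec(fabric, seed=2))
    res = analyse_volume(vol)
    field = res["field"]
    high = filter_high(field, 0.65)
    print(f"{fabric:9s} ({story}):")
    print(f"  defined VOI samples : {len(field.defined_samples())}")
    print(f"  Ani.M (modal DA)    : {res['Ani.M']:.3f}")
    print(f"  samples with DA>=0.65: {len(high.samples)}")
    for region in coherence(high):
        c = "undefined" if region.coherence is None else f"{region.coherence:.2f}"
        print(f"  axis coherence, {region.region:8s} third: {c}")

print("\nAni.M above ~0.4 with many coherent high-DA regions is the")
print("terrestrial signature; a low mode with few high-DA samples is the")
print("aquatic/semi-aquatic signature.")
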