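# osteofabric

Whole-bone trabecular anisotropy mapping and midshaft compactness
profiling for µCT scans of long bones — the desk toolkit for inferring
locomotor mode (aquatic vs terrestrial) from limb-bone inner structure,
with a synthetic phantom generator so every stage is testable without
scan data.

## The problem

Bone remodels along its habitual loads (bone functional adaptation).
In terrestrial limbs, gravity and ground-reaction forces align the
trabecular struts with the long axis and keep the midshaft medullary
cavity open; in aquatic limbs the struts stay disordered and the cavity
fills with bone. Two quantitative readouts capture this:

**Fabric anisotropy.** Over a cubic lattice of overlapping spherical
volumes of interest (pitch *s*, radius of influence *r* = *s*, hence
50% overlap; *s* = 500 µm, or 3 × Tb.Th when the mean trabecular width
exceeds 167 µm), the surface normals **n** of the trabecular bone in
each VOI form the orientation tensor

  C = ⟨ n nᵀ ⟩,  tr C = 1,  λ₁ ≥ λ₂ ≥ λ₃

For rod-like struts the normals avoid the strut axis, so the
eigenvector of λ₃ is the material direction and the degree of
anisotropy is DA = 1 − λ₃/λ₁ ∈ [0, 1] (0 isotropic, 1 aligned).
Undefined VOIs carry the sentinel DA = 0 and are discarded before
histogramming; the modal bin centre of the zero-excluded histogram is
the whole-element summary **Ani.M**. A mean-intercept-length (MIL)
estimator is included as an independent oracle.

**Midshaft compactness.** The binarised midshaft section, divided into
60 angular sectors × 51 radial bins about its centre, yields a radial
compactness profile fitted by

  C(d) = Min + (Max − Min) / (1 + exp((P − d)/S))

with Min (R_min) the compactness at the bone centre, Max (R_max) the
cortical plateau, P the medullo-cortical transition radius and S its
spread. R_min > 0 (struts filling the cavity) is the aquatic
signature; a logistic discriminant on R_min makes the binary call.

Around these sit the standard morphometrics (BV, TV, BV/TV, Tt.Ar,
Ct.Ar, Ma.Ar, Ct.Ar/Tt.Ar, Ct.Th, Tb.Th, P–D, R/t), and a
correlation-matrix PCA pools everything across specimens with
locomotor-group overlap reports.

## Worked example

```sh
python examples/map_anisotropy.py
```

prints (abridged):

```
aligned   (terrestrial-like):
  defined VOI samples : 112
  Ani.M (modal DA)    : 0.925
  samples with DA>=0.65: 112
  axis coherence, proximal third: 0.99
isotropic (aquatic-like):
  defined VOI samples : 112
  Ani.M (modal DA)    : 0.325
  samples with DA>=0.65: 0
  axis coherence, proximal third: undefined
```

Two phantoms identical except for rod orientation: the aligned
(terrestrial-like) fabric pushes the modal degree of anisotropy to
0.93 with every VOI above the 0.65 high-anisotropy threshold and
near-perfect axis coherence, while the isotropic (aquatic-like) fabric
keeps the mode at 0.33 with no high-DA samples — the two ends of the
locomotor signature.
The other scripts in `examples/` walk the phantom generator, the
compactness fit and lifestyle call, the morphometry report, and the
group-level PCA.

A thin CLI mirrors the library for shell use:

```sh
osteofabric phantom --spec spec.yaml --out-gray vol.nrrd --out-labels gt.nrrd --seed 17
osteofabric segment --in vol.nrrd --out labels.nrrd
osteofabric map-anisotropy --labels labels.nrrd --out field.csv --hist hist.csv
osteofabric run --config run.yaml     # full pipeline with caching
```

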