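"""Correlation-matrix PCA over a synthetic locomotor cohort.

Builds a feature table for three groups of synthetic specimens whose
compactness and anisotropy variables mimic the aquatic / semi-aquatic /
terrestrial gradient, runs the correlation PCA and prints the explained
variance, the top loadings, and the axis-aligned group-overlap report
used to place unknown (fossil) specimens.
"""

import numpy as np
import pandas as pd

from osteofabric.multivariate import assemble_features, group_overlap, pca_correlation

rng = np.random.default_rng(7)
rows, groups = [], {}
profiles = {
    "aquatic": dict(rmin=0.55, anim=0.28, ctar=0.45),
    "semi-aquatic": dict(rmin=0.35, anim=0.33, ctar=0.55),
    "terrestrial": dict(rmin=0.05, anim=0.55, ctar=0.75),
}
for group, p in profiles.items():
    for i in range(5):
        sid = f"{group[:4]}_{i}"
        rows.append(
            {
                "specimen": sid,
                "Rmin": p["rmin"] + rng.normal(0, 0.05),
                "Ani.M": p["anim"] + rng.normal(0, 0.04),
                "Ct.Ar/Tt.Ar": p["ctar"] + rng.normal(0, 0.05),
                "BV/TV": rng.normal(0.35, 0.05),
                "Tb.Th": rng.normal(0.12, 0.02),
            }
        )
        groups[sid] = group

features = pd.DataFrame(rows).set_index("specimen")
table = assemble_features([features], groups)
res = pca_correlation(table)

print("explained variance:", np.round(res.explained_variance, 3))
print("\nPC1 loadings (the locomotor axis):")
print(res.loadings["PC1"].round(3).to_string())

report = group_overlap(res, table.groups, axes=("PC1", "PC2"))
print("\ngroup overlap on (PC1, PC2):")
print(report[["group_a", "group_b", "overlap_both_axes"]].to_string(index=False))
print("\nGroups that do not overlap in both axes are separable in the")
print("ordination; fossils landing inside the aquatic envelope read as aquatic.")
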