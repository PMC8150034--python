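"""Correlation-matrix PCA over the combined morphometric variable table.

Specimens (rows) carry a locomotor group label; variables (columns) mix
volumetric metrics, compactness-profile parameters and the whole-bone
modal anisotropy.  The PCA standardises each variable (correlation
matrix), so unit choices drop out, and group separation is assessed by
axis-aligned score-range overlap on component pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "PCAResult",
    "assemble_features",
    "pca_correlation",
    "group_overlap",
    "GROUPS",
]

GROUPS = ("aquatic", "semi-aquatic", "terrestrial", "fossil")

DEFAULT_VARIABLES = [
    "TV", "BV", "Tt.Ar", "Ct.Ar", "Ma.Ar", "Ct.Ar/Tt.Ar", "Ct.Th", "Tb.Th",
    "P-D", "Cg", "Rmin", "Rmax", "P", "S", "Ani.M",
]


@dataclass
class FeatureTable:
    data: pd.DataFrame  # specimens x variables, numeric
    groups: pd.Series  # specimen -> group label
    imputed: pd.DataFrame  # boolean mask of mean-imputed cells

    def complete_cases(self) -> "FeatureTable":
        keep = ~self.imputed.any(axis=1)
        return FeatureTable(
            data=self.data.loc[keep],
            groups=self.groups.loc[keep],
            imputed=self.imputed.loc[keep],
        )


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # variables x components
    scores: pd.DataFrame  # specimens x components
    explained_variance: np.ndarray  # fraction per component
    dropped: list[str]  # zero-variance / too-missing columns removed


def assemble_features(
    metric_frames: list[pd.DataFrame],
    group_map: dict[str, str],
    max_missing_frac: float = 0.5,
) -> FeatureTable:
    """Join per-module metric tables (indexed by specimen id) into one.

    Columns missing in more than half the specimens are dropped with a
    warning; remaining gaps are mean-imputed within column and flagged so
    a complete-case analysis can be run alongside.
    """
    frames = []
    for f in metric_frames:
        f = f.copy()
        if f.index.has_duplicates:
            raise ValueError(f"duplicate specimen ids: {sorted(f.index[f.index.duplicated()])}")
        frames.append(f)
    joined = pd.concat(frames, axis=1, join="outer")
    if joined.columns.has_duplicates:
        raise ValueError("duplicate variable columns across metric files")
    joined = joined.loc[joined.index.intersection(list(group_map))]
    unknown = set(group_map.values()) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    missing_frac = joined.isna().mean()
    drop = missing_frac[missing_frac > max_missing_frac].index.tolist()
    if drop:
        warnings.warn(f"dropping columns with >50% missing: {drop}", stacklevel=2)
        joined = joined.drop(columns=drop)
    imputed = joined.isna()
    joined = joined.fillna(joined.mean())
    groups = pd.Series({k: group_map[k] for k in joined.index}, name="group")
    return FeatureTable(data=joined, groups=groups, imputed=imputed)


def pca_correlation(table: FeatureTable | pd.DataFrame) -> PCAResult:
    """PCA on the correlation matrix (z-scored variables).

    Component signs are fixed so the largest-magnitude loading in each
    column is positive; explained-variance fractions sum to 1 over all
    retained components.
    """
    data = table.data if isinstance(table, FeatureTable) else table
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("PCA needs at least 2 specimens and 2 variables")
    sd = data.std(ddof=1)
    dropped = sd[sd == 0].index.tolist()
    if dropped:
        warnings.warn(f"dropping zero-variance columns: {dropped}", stacklevel=2)
        data = data.drop(columns=dropped)
    z = (data - data.mean()) / data.std(ddof=1)
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(evecs.shape[1]):
        k = np.argmax(np.abs(evecs[:, j]))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    comps = [f"PC{i + 1}" for i in range(len(evals))]
    loadings = pd.DataFrame(evecs, index=data.columns, columns=comps)
    scores = pd.DataFrame(z.to_numpy() @ evecs, index=data.index, columns=comps)
    explained = evals / evals.sum()
    return PCAResult(
        loadings=loadings, scores=scores, explained_variance=explained, dropped=dropped
    )


def group_overlap(
    result: PCAResult,
    groups: pd.Series,
    axes: tuple[str, str] = ("PC1", "PC4"),
) -> pd.DataFrame:
    """Axis-aligned score-range overlap for every group pair.

    Two groups "overlap in both axes" when their score intervals
    intersect on *each* of the two requested components.  Singleton
    groups contribute a point interval (noted in the report).
    """
    rows = []
    names = [g for g in groups.unique()]
    for i, ga in enumerate(names):
        for gb in names[i + 1 :]:
            entry: dict = {"group_a": ga, "group_b": gb}
            both = True
            for ax in axes:
                sa = result.scores.loc[groups[groups == ga].index, ax]
                sb = result.scores.loc[groups[groups == gb].index, ax]
                ov = (sa.min() <= sb.max()) and (sb.min() <= sa.max())
                entry[f"overlap_{ax}"] = bool(ov)
                both &= ov
            entry["overlap_both_axes"] = both
            entry["singleton"] = bool(
                (groups == ga).sum() == 1 or (groups == gb).sum() == 1
            )
            rows.append(entry)
    return pd.DataFrame(rows)
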