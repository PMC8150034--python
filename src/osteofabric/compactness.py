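"""Midshaft compactness-profile analysis.

A binarised transverse midshaft section is divided into angular sectors
and radial bins about a reference centre; the occupied-bone fraction per
cell is the compactness profile C(d), with d the radial position
normalised per sector (0 at the centre, 1 at the periosteal boundary).
A four-parameter sigmoid

    C(d) = Min + (Max - Min) / (1 + exp((P - d) / S))

is fitted globally and per sector: Min (Rmin) is the compactness at the
bone centre, Max (Rmax) the compactness of the cortex, P the radial
position of the medullo-cortical transition and S the spread of that
transition (the slope at P is (Max - Min) / (4 S)).  Open medullary
cavities give Rmin near 0; cavities filled with trabeculae give Rmin
clearly above 0 — the basis of the aquatic/terrestrial discriminant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "CompactnessProfile",
    "SigmoidFit",
    "SectionCentres",
    "LifestyleCall",
    "binarize_midshaft",
    "compute_centres",
    "radial_profile",
    "fit_sigmoid",
    "observed_compactness",
    "classify_lifestyle",
    "fit_lifestyle_discriminant",
    "sigmoid",
]

DEFAULT_SECTORS = 60
DEFAULT_RADIAL_BINS = 51


@dataclass
class CompactnessProfile:
    compactness: np.ndarray  # (n_sectors, n_radial_bins), NaN where undefined
    pixel_counts: np.ndarray  # pixels per cell
    bone_counts: np.ndarray  # bone pixels per cell
    centre: np.ndarray  # pixel coordinates of the reference centre
    n_sectors: int = DEFAULT_SECTORS
    n_radial_bins: int = DEFAULT_RADIAL_BINS

    @property
    def radial_centres(self) -> np.ndarray:
        edges = np.linspace(0.0, 1.0, self.n_radial_bins + 1)
        return 0.5 * (edges[:-1] + edges[1:])


@dataclass
class SigmoidFit:
    min_asymptote: float  # Rmin
    max_asymptote: float  # Rmax
    p: float  # transition position
    s: float  # spread (reciprocal-slope) parameter
    rss: float
    scope: str = "global"
    degenerate: bool = False
    per_sector: Optional[dict] = None  # mean/sd/median per parameter


@dataclass
class SectionCentres:
    section_centre: np.ndarray
    medullary_centre: np.ndarray
    ontogenetic_centre: np.ndarray


@dataclass
class LifestyleCall:
    score: float
    call: str  # "aquatic" | "terrestrial"
    coefficients_id: str


def sigmoid(d: np.ndarray, mn: float, mx: float, p: float, s: float) -> np.ndarray:
    # clipped exponent: steep fits (tiny S) otherwise overflow float64
    z = np.clip((p - d) / s, -700.0, 700.0)
    return mn + (mx - mn) / (1.0 + np.exp(z))


def binarize_midshaft(gray_slice: np.ndarray, method: str = "otsu") -> np.ndarray:
    """Binarise a midshaft slice and keep the largest connected section.

    Interior holes are *not* filled (they are the medullary signal);
    already-binary input passes through unchanged apart from the
    largest-component rule.
    """
    img = np.asarray(gray_slice)
    if img.dtype == bool:
        fg = img
    else:
        vals = np.unique(img)
        if len(vals) <= 2:
            fg = img > vals[0] if len(vals) == 2 else img > 0
        elif method == "otsu":
            from .preprocess import otsu_threshold

            fg = img > otsu_threshold(img)
        else:
            raise ValueError(f"unknown binarisation method {method!r}")
    if not fg.any():
        raise ValueError("empty foreground after binarisation")
    comp, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=bool))
    if n > 1:
        sizes = np.bincount(comp.ravel())
        sizes[0] = 0
        fg = comp == np.argmax(sizes)
    return fg


def _filled(section: np.ndarray) -> np.ndarray:
    return ndimage.binary_fill_holes(section)


def compute_centres(
    section: np.ndarray,
    n_sectors: int = DEFAULT_SECTORS,
    n_radial_bins: int = DEFAULT_RADIAL_BINS,
    max_steps: int = 200,
) -> SectionCentres:
    """Section, medullary and ontogenetic centres of a binary section.

    The section centre is the centroid of the filled periosteal region;
    the medullary centre is the centroid of the interior non-bone pixels
    (falling back to the section centre for solid sections).  The
    ontogenetic centre minimises the total residual of per-sector sigmoid
    fits, found by single-pixel coordinate descent from the section
    centre — an operational reading of the growth-centre concept.
    """
    section = np.asarray(section, dtype=bool)
    if not section.any():
        raise ValueError("empty section")
    filled = _filled(section)
    section_centre = np.array(ndimage.center_of_mass(filled))
    interior = filled & ~section
    if interior.any():
        medullary_centre = np.array(ndimage.center_of_mass(interior))
    else:
        medullary_centre = section_centre.copy()

    def total_rss(centre: np.ndarray) -> float:
        if not filled[tuple(np.clip(np.round(centre).astype(int), 0, np.array(section.shape) - 1))]:
            return np.inf
        prof = radial_profile(section, centre, n_sectors, n_radial_bins)
        try:
            fit = fit_sigmoid(prof, scope="global")
        except RuntimeError:
            return np.inf
        return fit.rss

    centre = section_centre.copy()
    best = total_rss(centre)
    moves = [np.array(m) for m in ((1, 0), (-1, 0), (0, 1), (0, -1))]
    for _ in range(max_steps):
        improved = False
        for m in moves:
            cand = centre + m
            val = total_rss(cand)
            if val < best - 1e-12:
                centre, best, improved = cand, val, True
                break
        if not improved:
            break
    return SectionCentres(
        section_centre=section_centre,
        medullary_centre=medullary_centre,
        ontogenetic_centre=centre,
    )


def radial_profile(
    section: np.ndarray,
    centre: np.ndarray | tuple[float, float],
    n_sectors: int = DEFAULT_SECTORS,
    n_radial_bins: int = DEFAULT_RADIAL_BINS,
) -> CompactnessProfile:
    """Sector x radial-bin compactness of a binary section.

    Pixels are assigned to sectors by angle about the centre; within each
    sector radial distances are normalised to that sector's outermost
    bone pixel, so d = 1 tracks the periosteal boundary even for
    non-circular sections.  Cells without pixels are NaN (excluded from
    fits).
    """
    section = np.asarray(section, dtype=bool)
    centre = np.asarray(centre, dtype=float)
    filled = _filled(section)
    if not filled.any():
        raise ValueError("empty section")
    # permissive centre check: damaged sections (missing wedges) leave the
    # geometric centre outside the filled region, which is fine — the
    # affected sectors simply come back undefined
    lo = np.argwhere(filled).min(axis=0) - 1
    hi = np.argwhere(filled).max(axis=0) + 1
    if not ((lo <= centre).all() and (centre <= hi).all()):
        raise ValueError("centre must lie inside the section's bounding box")
    ii, jj = np.nonzero(filled)
    di = ii - centre[0]
    dj = jj - centre[1]
    r = np.hypot(di, dj)
    theta = np.mod(np.arctan2(dj, di), 2.0 * np.pi)
    sector = np.minimum((theta / (2.0 * np.pi) * n_sectors).astype(int), n_sectors - 1)
    bone = section[ii, jj]
    # per-sector periosteal radius: outermost bone pixel
    rmax = np.zeros(n_sectors)
    np.maximum.at(rmax, sector[bone], r[bone])
    rmax[rmax == 0] = np.nan
    rel = r / rmax[sector]
    valid = np.isfinite(rel) & (rel <= 1.0)
    rbin = np.minimum(
        (rel[valid] * n_radial_bins).astype(int), n_radial_bins - 1
    )
    sec_v = sector[valid]
    bone_v = bone[valid]
    counts = np.zeros((n_sectors, n_radial_bins))
    bones = np.zeros((n_sectors, n_radial_bins))
    np.add.at(counts, (sec_v, rbin), 1)
    np.add.at(bones, (sec_v, rbin), bone_v.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        comp = np.where(counts > 0, bones / np.maximum(counts, 1), np.nan)
    comp[counts == 0] = np.nan
    return CompactnessProfile(
        compactness=comp,
        pixel_counts=counts,
        bone_counts=bones,
        centre=centre,
        n_sectors=n_sectors,
        n_radial_bins=n_radial_bins,
    )


_STARTS = (
    # (Min, Max, P, S): spread over open and filled morphologies
    (0.0, 1.0, 0.7, 0.05),
    (0.0, 1.0, 0.5, 0.1),
    (0.3, 0.9, 0.6, 0.02),
    (0.1, 1.0, 0.8, 0.2),
    (0.5, 1.0, 0.5, 0.05),
)


def _fit_cells(d: np.ndarray, c: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, float]:
    """Weighted bounded least-squares sigmoid fit with multi-start."""
    sw = np.sqrt(w)

    def resid(params):
        return sw * (sigmoid(d, *params) - c)

    lower = [0.0, 0.0, 0.0, 1e-4]
    upper = [1.0, 1.0, 1.0, 5.0]
    best = None
    for start in _STARTS:
        x0 = np.clip(start, lower, upper)
        try:
            res = optimize.least_squares(
                resid, x0, bounds=(lower, upper), method="trf", xtol=1e-12, ftol=1e-12
            )
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[1]:
            best = (res.x, rss)
    if best is None:
        raise RuntimeError("sigmoid fit failed from all starts")
    return best


def fit_sigmoid(
    profile: CompactnessProfile,
    scope: str = "global",
    min_cells: int = 8,
    weight_by_pixels: bool = True,
) -> SigmoidFit:
    """Fit the four-parameter sigmoid to a compactness profile.

    ``scope='global'`` pools all defined cells (weighted by their pixel
    counts so cells summarising more bone count more); ``scope='per-
    sector'`` fits each sector separately and reports the across-sector
    mean of each parameter with SD and median in ``per_sector``.  A fit
    whose asymptotes nearly coincide is flagged degenerate (P and S are
    then meaningless).
    """
    comp = profile.compactness
    d_centres = profile.radial_centres
    if scope == "global":
        mask = np.isfinite(comp)
        if mask.sum() < min_cells:
            raise RuntimeError("too few defined cells for a global fit")
        d = np.broadcast_to(d_centres, comp.shape)[mask]
        c = comp[mask]
        w = profile.pixel_counts[mask] if weight_by_pixels else np.ones(mask.sum())
        params, rss = _fit_cells(d, c, w)
        mn, mx, p, s = params
        return SigmoidFit(
            min_asymptote=float(mn),
            max_asymptote=float(mx),
            p=float(p),
            s=float(s),
            rss=rss,
            scope="global",
            degenerate=bool(mx - mn < 0.05),
        )
    if scope != "per-sector":
        raise ValueError(f"unknown scope {scope!r}")
    rows = []
    for sec in range(profile.n_sectors):
        mask = np.isfinite(comp[sec])
        if mask.sum() < min_cells:
            continue
        d = d_centres[mask]
        c = comp[sec][mask]
        w = profile.pixel_counts[sec][mask] if weight_by_pixels else np.ones(mask.sum())
        try:
            params, rss = _fit_cells(d, c, w)
        except RuntimeError:
            continue
        rows.append((*params, rss))
    if not rows:
        raise RuntimeError("no sector admitted a sigmoid fit")
    arr = np.asarray(rows)
    mean = arr.mean(axis=0)
    per_sector = {
        "mean": dict(zip(("Rmin", "Rmax", "P", "S"), mean[:4].tolist())),
        "sd": dict(zip(("Rmin", "Rmax", "P", "S"), arr[:, :4].std(axis=0).tolist())),
        "median": dict(
            zip(("Rmin", "Rmax", "P", "S"), np.median(arr[:, :4], axis=0).tolist())
        ),
        "n_sectors_fit": len(rows),
    }
    return SigmoidFit(
        min_asymptote=float(mean[0]),
        max_asymptote=float(mean[1]),
        p=float(mean[2]),
        s=float(mean[3]),
        rss=float(arr[:, 4].sum()),
        scope="per-sector",
        degenerate=bool(mean[1] - mean[0] < 0.05),
        per_sector=per_sector,
    )


def observed_compactness(section: np.ndarray) -> float:
    """Global observed compactness Cg: bone pixels over periosteal pixels."""
    section = np.asarray(section, dtype=bool)
    if not section.any():
        raise ValueError("empty section")
    filled = _filled(section)
    return float(section.sum() / filled.sum())


@dataclass
class DiscriminantCoefficients:
    intercept: float
    coefficients: dict[str, float]  # variable name -> weight
    coefficients_id: str = "user"


def classify_lifestyle(
    fit: SigmoidFit | dict,
    coefficients: DiscriminantCoefficients,
) -> LifestyleCall:
    """Binary aquatic/terrestrial call from compactness variables.

    ``score = intercept + sum(coef * variable)``; the default refit
    coefficient sets use Rmin only (the compactness at the bone centre,
    the dominant lifestyle signal).  ``score > 0`` calls terrestrial; the
    boundary score of exactly 0 is called aquatic.
    """
    values = (
        {"Rmin": fit.min_asymptote, "Rmax": fit.max_asymptote, "P": fit.p, "S": fit.s}
        if isinstance(fit, SigmoidFit)
        else dict(fit)
    )
    score = coefficients.intercept
    for name, coef in coefficients.coefficients.items():
        if name not in values:
            raise ValueError(f"discriminant variable {name!r} missing from fit")
        score += coef * values[name]
    call = "terrestrial" if score > 0 else "aquatic"
    return LifestyleCall(score=float(score), call=call, coefficients_id=coefficients.coefficients_id)


def fit_lifestyle_discriminant(
    rmin_values: np.ndarray,
    labels: list[str],
    coefficients_id: str = "refit",
) -> DiscriminantCoefficients:
    """Refit a logistic discriminant on labelled (Rmin, lifestyle) data.

    ``labels`` entries are "aquatic" or "terrestrial".  Returns
    coefficients on the Rmin variable such that positive score means
    terrestrial.  Ships in place of unpublished reference constants: the
    training data are the caller's own labelled sections or phantoms.
    """
    from sklearn.linear_model import LogisticRegression

    y = np.array([1 if l == "terrestrial" else 0 for l in labels])
    X = np.asarray(rmin_values, dtype=float).reshape(-1, 1)
    if len(np.unique(y)) < 2:
        raise ValueError("need both lifestyle classes to refit the discriminant")
    # effectively unpenalised fit; huge C avoids version-dependent penalty API
    model = LogisticRegression(C=1e6, max_iter=1000)
    model.fit(X, y)
    return DiscriminantCoefficients(
        intercept=float(model.intercept_[0]),
        coefficients={"Rmin": float(model.coef_[0, 0])},
        coefficients_id=coefficients_id,
    )
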