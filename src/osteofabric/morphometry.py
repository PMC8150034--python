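"""Standard 2-D and 3-D bone morphometry.

Cross-sectional metrics (Tt.Ar, Ct.Ar, Ma.Ar, Ct.Ar/Tt.Ar, R/t), volume
fractions (BV, TV, BV/TV), model-independent local thickness (Ct.Th,
Tb.Th) by the largest-inscribed-sphere definition, and proximal--distal
length (P--D).  Areas are mm², volumes mm³, thicknesses and lengths mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import (
    LABEL_CAVITY,
    LABEL_CORTICAL,
    LABEL_TRABECULAR,
    LabelVolume,
)

__all__ = [
    "CrossSectionMetrics",
    "section_areas",
    "volume_fractions",
    "local_thickness",
    "pd_length",
    "metrics_table",
]


@dataclass
class CrossSectionMetrics:
    tt_ar: float  # total subperiosteal area, mm^2
    ct_ar: float  # cortical area, mm^2
    ma_ar: float  # marrow/cavity area, mm^2
    tb_ar: float  # trabecular area within the section, mm^2
    ct_ar_frac: float  # Ct.Ar / Tt.Ar
    r_over_t: float  # mean outer radius / mean cortical thickness


def section_areas(label_slice: np.ndarray, spacing_um: float) -> CrossSectionMetrics:
    """Areas of one transverse section from voxel counts.

    ``R`` for the stiffness score R/t is the equivalent-circle radius
    ``sqrt(Tt.Ar/pi)``; ``t`` is the in-plane cortical local thickness of
    the slice.
    """
    label_slice = np.asarray(label_slice)
    if label_slice.ndim != 2:
        raise ValueError("expected a 2-D label slice")
    px = float(spacing_um) ** 2 * 1e-6  # µm² → mm²
    ct = int((label_slice == LABEL_CORTICAL).sum())
    tb = int((label_slice == LABEL_TRABECULAR).sum())
    ma = int((label_slice == LABEL_CAVITY).sum())
    if ct + tb == 0:
        raise ValueError("slice contains no bone")
    tt_ar = (ct + tb + ma) * px
    ct_ar = ct * px
    ma_ar = ma * px
    r_eq = np.sqrt(tt_ar / np.pi)  # mm
    if ct:
        thick, t_mean = local_thickness(
            (label_slice == LABEL_CORTICAL), spacing_um
        )
        r_over_t = r_eq / t_mean if t_mean > 0 else np.nan
    else:
        r_over_t = np.nan
    return CrossSectionMetrics(
        tt_ar=tt_ar,
        ct_ar=ct_ar,
        ma_ar=ma_ar,
        tb_ar=tb * px,
        ct_ar_frac=ct_ar / tt_ar,
        r_over_t=float(r_over_t),
    )


def volume_fractions(label: LabelVolume, region: str = "whole") -> tuple[float, float, float]:
    """(BV, TV, BV/TV) in mm³ for the requested region.

    ``region='whole'``: TV spans the whole bone (labels 1, 2, 3), BV is all
    bone (1, 2).  ``region='trabecular-compartment'``: TV spans the
    endosteal compartment (2, 3), BV is trabecular bone only (2).
    """
    vx = float(np.prod(label.spacing)) * 1e-9  # µm³ → mm³
    if region == "whole":
        tv_mask = label.mask([LABEL_CORTICAL, LABEL_TRABECULAR, LABEL_CAVITY])
        bv_mask = label.mask([LABEL_CORTICAL, LABEL_TRABECULAR])
    elif region == "trabecular-compartment":
        tv_mask = label.mask([LABEL_TRABECULAR, LABEL_CAVITY])
        bv_mask = label.mask([LABEL_TRABECULAR])
    else:
        raise ValueError(f"unknown region {region!r}")
    tv_n = int(tv_mask.sum())
    if tv_n == 0:
        raise ValueError(f"region {region!r} is empty")
    bv = bv_mask.sum() * vx
    tv = tv_n * vx
    return float(bv), float(tv), float(bv / tv)


def local_thickness(mask: np.ndarray, spacing_um: float) -> tuple[np.ndarray, float]:
    """Largest-inscribed-sphere local thickness map and its mean (mm).

    The thickness at a point is the diameter of the largest sphere that
    both contains the point and fits entirely inside the structure.
    Computed by sweeping sphere radii from the Euclidean distance
    transform downward: the morphological opening with radius ``r``
    marks exactly the points covered by some inscribed sphere of radius
    ``>= r``.  Works in 2-D (circles) and 3-D (spheres).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if mask.all():
        raise ValueError("mask fills the whole grid; thickness is unbounded")
    # Digital spheres are voxel balls: the ball at centre c with integer
    # radius m = floor(dt(c) - eps) is the largest set of voxels within
    # centre-distance m that fits inside the structure, and its diameter is
    # 2m + 1 voxels (a lone voxel is a one-voxel sphere, m = 0).  The sweep
    # runs over m descending; a voxel belongs to a ball when its centre is
    # within m + 0.5 of the ball centre (half a voxel of slack, so surface
    # voxels join the largest ball they touch).  Structures touching the
    # array faces are treated as continuing beyond them.
    dt = ndimage.distance_transform_edt(mask)
    m_map = np.floor(dt - 1e-9)  # integer voxel-ball radius at each centre
    radii = np.unique(m_map[mask]).astype(int)[::-1]
    thickness = np.zeros(mask.shape)
    for m in radii:
        seeds = m_map >= m
        reach = ndimage.distance_transform_edt(~seeds) <= m + 0.5 + 1e-9
        reach &= mask
        update = reach & (thickness == 0)
        thickness[update] = 2.0 * m + 1.0
        if not (thickness[mask] == 0).any():
            break
    thickness[~mask] = 0.0
    thickness_mm = thickness * float(spacing_um) * 1e-3
    return thickness_mm, float(thickness_mm[mask].mean())


def pd_length(mask: np.ndarray, spacing_um: float) -> float:
    """Proximal--distal extent (mm): occupied span along the slice axis."""
    mask = np.asarray(mask, dtype=bool)
    occupied = np.flatnonzero(mask.any(axis=(0, 1)))
    if occupied.size == 0:
        raise ValueError("empty mask")
    n = occupied[-1] - occupied[0] + 1
    return float(n * spacing_um * 1e-3)


def metrics_table(
    label: LabelVolume, midshaft_index: int | None = None
) -> dict[str, float]:
    """All scalar morphometric variables for one specimen.

    "Average" areas are means over the diaphyseal slices between 25% and
    75% of the P--D span; the midshaft-only values are reported alongside
    (suffix ``.mid``) when a midshaft index is given.
    """
    sp = float(label.spacing[0])
    whole = label.mask([LABEL_CORTICAL, LABEL_TRABECULAR, LABEL_CAVITY])
    pd_mm = pd_length(whole, sp)
    occupied = np.flatnonzero(whole.any(axis=(0, 1)))
    k0, k1 = occupied[0], occupied[-1]
    lo = k0 + int(0.25 * (k1 - k0))
    hi = k0 + int(0.75 * (k1 - k0))
    rows = []
    for k in range(lo, hi + 1):
        sl = label.labels[:, :, k]
        if (np.isin(sl, [LABEL_CORTICAL, LABEL_TRABECULAR])).any():
            rows.append(section_areas(sl, sp))
    if not rows:
        raise ValueError("no bone-bearing diaphyseal slices")
    mean = lambda attr: float(np.mean([getattr(r, attr) for r in rows]))
    bv, tv, bvtv = volume_fractions(label, "whole")
    out = {
        "Tt.Ar": mean("tt_ar"),
        "Ct.Ar": mean("ct_ar"),
        "Ma.Ar": mean("ma_ar"),
        "Ct.Ar/Tt.Ar": mean("ct_ar_frac"),
        "BV": bv,
        "TV": tv,
        "BV/TV": bvtv,
        "P-D": pd_mm,
        "R/t": mean("r_over_t"),
    }
    try:
        bv_c, tv_c, bvtv_c = volume_fractions(label, "trabecular-compartment")
        out["BV/TV.compartment"] = bvtv_c
    except ValueError:
        out["BV/TV.compartment"] = float("nan")
    cortical = label.labels == LABEL_CORTICAL
    if cortical.any():
        _, out["Ct.Th"] = local_thickness(cortical, sp)
    else:
        out["Ct.Th"] = float("nan")
    trab = label.labels == LABEL_TRABECULAR
    if trab.any():
        _, out["Tb.Th"] = local_thickness(trab, sp)
    else:
        out["Tb.Th"] = float("nan")
    if midshaft_index is not None:
        m = section_areas(label.labels[:, :, midshaft_index], sp)
        out.update(
            {
                "Tt.Ar.mid": m.tt_ar,
                "Ct.Ar.mid": m.ct_ar,
                "Ma.Ar.mid": m.ma_ar,
                "Ct.Ar/Tt.Ar.mid": m.ct_ar_frac,
                "R/t.mid": m.r_over_t,
            }
        )
    return out
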