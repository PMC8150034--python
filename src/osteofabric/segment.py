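"""Cortical / trabecular / cavity segmentation and midshaft selection.

The compartment labelling follows the dual-surface logic of automatic
cortical-shell segmentation: the periosteal surface is recovered by a
morphological closing of the bone mask, the endosteal region by a closing
of the internal non-bone space, and trabecular bone is the bone that sits
inside the endosteal region.  One interpretable knob — the closing radius
— controls how large a gap is still considered part of a surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import perimeter_crofton

from .volume_io import (
    LABEL_CAVITY,
    LABEL_CORTICAL,
    LABEL_TRABECULAR,
    LabelVolume,
    VoxelVolume,
)

__all__ = [
    "SegmentationConfig",
    "MidshaftSelection",
    "align_long_axis",
    "segment_compartments",
    "whole_bone_mask",
    "denoise_trabecular",
    "find_midshaft",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class SegmentationConfig:
    """Knobs of the compartment segmentation.

    ``shell_closing_radius_vox`` is the closing radius in voxels (default
    6); it must exceed the typical trabecular strut diameter for the
    endosteal closing to bridge the voids between struts, and stay well
    below the cortical thickness so the shell survives.  ``min_component``
    is the smallest 26-connected trabecular component (in voxels) kept by
    the denoiser.
    """

    shell_closing_radius_vox: float = 6.0
    min_component: int = 27
    axis_align: bool = True

    def __post_init__(self) -> None:
        if self.shell_closing_radius_vox <= 0:
            raise ValueError("closing radius must be positive")
        if self.min_component < 1:
            raise ValueError("min_component must be >= 1")


@dataclass
class MidshaftSelection:
    """Result of the midshaft search along the slice axis."""

    slice_index: int
    circumference_profile: np.ndarray  # outer perimeter per slice, mm
    cortical_area_profile: np.ndarray  # Ct.Ar per slice, mm^2
    search_window: tuple[int, int]  # inclusive slice range examined
    qc: dict = field(default_factory=dict)


def _ball(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    x, y, z = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return x * x + y * y + z * z <= radius * radius


def _binary_closing(mask: np.ndarray, radius: float) -> np.ndarray:
    """Euclidean closing via distance transforms (fast for large balls).

    The input is padded with background first: without it the erosion
    pass has no outside reference at the array faces and the closing
    bleeds past the structure ends.
    """
    if radius <= 0:
        return mask
    p = int(np.ceil(radius)) + 1
    padded = np.pad(mask, p)
    # dilation: distance to mask <= r ; erosion: distance to complement > r
    dilated = ndimage.distance_transform_edt(~padded) <= radius
    closed = ndimage.distance_transform_edt(dilated) > radius
    return closed[tuple(slice(p, -p) for _ in mask.shape)]


def _close2d_stack(mask: np.ndarray, radius: float) -> np.ndarray:
    """Per-transverse-slice Euclidean closing + hole fill of the stack.

    The endosteal (trabecular + marrow) region is delimited slice-wise:
    in a transverse section the endosteal contour is convex or nearly so,
    so an in-plane closing bridges the voids between trabeculae without
    advancing into the wall, and — unlike a 3-D closing — cannot eat
    through the thin cortical caps at the bone ends, whose slices contain
    no internal space at all.  Requires the long axis on the slice axis.
    """
    out = np.zeros_like(mask)
    p = int(np.ceil(radius)) + 1
    for k in range(mask.shape[2]):
        sl = mask[:, :, k]
        if not sl.any():
            continue
        padded = np.pad(sl, p)
        dilated = ndimage.distance_transform_edt(~padded) <= radius
        closed = ndimage.distance_transform_edt(dilated) > radius
        out[:, :, k] = ndimage.binary_fill_holes(closed)[p:-p, p:-p]
    return out


def align_long_axis(
    mask: np.ndarray, grayscale: VoxelVolume | None = None, degeneracy_tol: float = 0.05
) -> dict:
    """Rotate a bone mask so its principal inertia axis is the slice axis.

    Returns a dict with ``rotation`` (3x3 matrix, world), ``mask`` (rotated,
    nearest-neighbour), ``grayscale`` (rotated trilinearly when given),
    ``angle_deg`` (applied rotation angle) and ``degenerate`` (True when
    the inertia tensor is near-isotropic and the identity was kept).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    idx = np.argwhere(mask).astype(np.float64)
    centroid = idx.mean(axis=0)
    centred = idx - centroid
    cov = centred.T @ centred / len(centred)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    # principal elongation axis = largest-eigenvalue eigenvector
    spread = (evals[2] - evals[0]) / max(evals[2], 1e-12)
    if spread < degeneracy_tol:
        return {
            "rotation": np.eye(3),
            "mask": mask,
            "grayscale": grayscale,
            "angle_deg": 0.0,
            "degenerate": True,
        }
    axis = evecs[:, 2]
    target = np.array([0.0, 0.0, 1.0])
    if axis @ target < 0:
        axis = -axis
    v = np.cross(axis, target)
    c = float(axis @ target)
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx / (1 + c)
    angle = float(np.degrees(np.arccos(np.clip(c, -1, 1))))
    if angle < 1.0:
        return {
            "rotation": np.eye(3),
            "mask": mask,
            "grayscale": grayscale,
            "angle_deg": 0.0,
            "degenerate": False,
        }
    rotated_mask = _rotate_volume(mask.astype(np.float32), rot, centroid, order=0) > 0.5
    rotated_gray = None
    if grayscale is not None:
        rotated_gray = grayscale.with_data(
            _rotate_volume(grayscale.data.astype(np.float32), rot, centroid, order=1)
        )
    return {
        "rotation": rot,
        "mask": rotated_mask,
        "grayscale": rotated_gray,
        "angle_deg": angle,
        "degenerate": False,
    }


def _rotate_volume(
    data: np.ndarray, rot: np.ndarray, centre: np.ndarray, order: int
) -> np.ndarray:
    # map output coords back through the inverse rotation about the centroid
    inv = rot.T
    offset = centre - inv @ centre
    return ndimage.affine_transform(
        data, inv, offset=offset, order=order, mode="constant", cval=0.0
    )


def segment_compartments(
    bone_mask: np.ndarray,
    spacing: np.ndarray | float,
    config: SegmentationConfig | None = None,
) -> LabelVolume:
    """Label a bone mask into cortical (1), trabecular (2) and cavity (3).

    Steps: (i) a 3-D closing of the bone mask recovers the periosteal
    surface; (ii) 6-connected hole filling yields the whole-bone region;
    (iii) the internal non-bone space, closed slice-wise in the
    transverse plane, defines the endosteal (trabecular + marrow)
    region; (iv) bone inside that region is trabecular, the rest
    cortical.  Expects the long axis on the slice axis (run
    :func:`align_long_axis` first on oblique scans).
    """
    config = config or SegmentationConfig()
    mask = np.asarray(bone_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty bone mask")
    spacing = np.atleast_1d(np.asarray(spacing, dtype=float))
    if spacing.size == 1:
        spacing = np.repeat(spacing, 3)
    r = config.shell_closing_radius_vox

    closed = _binary_closing(mask, r)
    whole = ndimage.binary_fill_holes(closed, structure=_STRUCT_6)
    inner_space = whole & ~mask
    if inner_space.any():
        trab_region = _close2d_stack(inner_space, r) & whole
    else:
        trab_region = np.zeros_like(mask)

    labels = np.zeros(mask.shape, dtype=np.uint8)
    labels[mask & ~trab_region] = LABEL_CORTICAL
    labels[mask & trab_region] = LABEL_TRABECULAR
    labels[inner_space] = LABEL_CAVITY
    return LabelVolume(labels, spacing)


def whole_bone_mask(label: LabelVolume) -> np.ndarray:
    """Union of cortical, trabecular and internal cavity: the filled bone."""
    return label.mask([LABEL_CORTICAL, LABEL_TRABECULAR, LABEL_CAVITY])


def denoise_trabecular(label: LabelVolume, min_component: int = 27) -> LabelVolume:
    """Drop small 26-connected trabecular specks into the cavity label.

    Components of label 2 smaller than ``min_component`` voxels are
    reassigned to label 3; everything else is untouched, so the total
    voxel count is conserved.
    """
    if min_component < 1:
        raise ValueError("min_component must be >= 1")
    trab = label.labels == LABEL_TRABECULAR
    if not trab.any():
        return label
    comp, n = ndimage.label(trab, structure=_STRUCT_26)
    sizes = np.bincount(comp.ravel())
    small = np.flatnonzero(sizes < min_component)
    small = small[small != 0]
    out = label.labels.copy()
    if small.size:
        out[np.isin(comp, small)] = LABEL_CAVITY
    return LabelVolume(out, label.spacing, label.origin)


def find_midshaft(label: LabelVolume, window_tol: float = 0.02) -> MidshaftSelection:
    """Locate the midshaft slice along the slice axis.

    The per-slice outer perimeter (Crofton estimator, mm) of the whole-bone
    mask is scanned for its minimum; the search window is the contiguous
    run of slices (containing the argmin) within ``window_tol`` of that
    minimum, and within the window the slice with the largest cortical
    area wins.  Ties break to the most central slice of the window.
    """
    whole = whole_bone_mask(label)
    n_slices = whole.shape[2]
    if n_slices < 10:
        raise ValueError("need at least 10 slices for a midshaft search")
    areas = whole.sum(axis=(0, 1))
    occupied = np.flatnonzero(areas)
    if occupied.size == 0:
        raise ValueError("no bone in any slice")
    # the narrowest-circumference search concerns the shaft: ragged end
    # slices and stray specks (area well below the typical section) are
    # excluded so a 1-pixel tip cannot win the perimeter minimum
    floor = 0.5 * np.median(areas[occupied])
    occupied = occupied[areas[occupied] >= floor]
    sp = label.spacing
    perim = np.full(n_slices, np.inf)
    ct_area = np.zeros(n_slices)
    px_area_mm2 = sp[0] * sp[1] * 1e-6
    for k in occupied:
        perim[k] = perimeter_crofton(whole[:, :, k], directions=4) * sp[0] * 1e-3
        ct_area[k] = (label.labels[:, :, k] == LABEL_CORTICAL).sum() * px_area_mm2
    kmin = int(np.argmin(perim))
    lim = perim[kmin] * (1 + window_tol)
    lo = kmin
    while lo - 1 >= 0 and perim[lo - 1] <= lim:
        lo -= 1
    hi = kmin
    while hi + 1 < n_slices and perim[hi + 1] <= lim:
        hi += 1
    window = np.arange(lo, hi + 1)
    best = ct_area[window].max()
    candidates = window[np.isclose(ct_area[window], best, rtol=1e-9, atol=1e-12)]
    centre = 0.5 * (lo + hi)
    slice_index = int(candidates[np.argmin(np.abs(candidates - centre))])
    return MidshaftSelection(
        slice_index=slice_index,
        circumference_profile=perim,
        cortical_area_profile=ct_area,
        search_window=(lo, hi),
        qc={"perimeter_min_mm": float(perim[kmin]), "argmin_slice": kmin},
    )
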