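"""Whole-bone trabecular anisotropy mapping.

A regular cubic lattice of overlapping spherical volumes of interest
(VOIs) is laid over the trabecular compartment.  In each VOI the surface
normals of the trabecular bone are collected and their second-moment
(covariance) tensor is eigen-analysed: for rod-like struts the normals
avoid the strut axis, so the eigenvector of the *smallest* eigenvalue is
the material long axis, and the degree of anisotropy

    DA = 1 - lambda_min / lambda_max           (0 isotropic, 1 aligned)

summarises how organised the local structure is.  VOIs with too few
normals carry the sentinel value DA = 0, which downstream histograms
must discard — the whole-element summary statistic is the modal bin of
the zero-excluded DA histogram (Ani.M).

A mean-intercept-length (MIL) estimator over the same VOIs is included
as an independent oracle for cross-validating the surface-normal fabric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy import ndimage

from .volume_io import LABEL_TRABECULAR, LabelVolume

__all__ = [
    "SamplingLattice",
    "FabricSample",
    "AnisotropyField",
    "DAHistogram",
    "CoherenceSummary",
    "build_lattice",
    "surface_normals",
    "fabric_tensor",
    "map_anisotropy",
    "da_histogram",
    "filter_high",
    "coherence",
    "mil_fabric",
]

#: trabecular width (µm) above which the lattice pitch follows 3x Tb.Th
ADAPTIVE_TBTH_CUTOVER_UM = 500.0 / 3.0  # = 166.7, i.e. 167 µm to the nearest µm
DEFAULT_SPACING_UM = 500.0
DEFAULT_MIN_NORMALS = 50
DEFAULT_HIGH_DA = 0.65


@dataclass
class SamplingLattice:
    """Cubic grid of spherical VOI centres covering the trabecular ROI.

    With radius of influence equal to the pitch (``radius == spacing``)
    adjacent VOIs overlap by 50% of their diameter:
    ``(2r - s) / (2r) = 0.5``.
    """

    spacing: float  # sample pitch s, µm
    radius: float  # radius of influence r, µm
    centres: np.ndarray  # (n, 3) world coordinates, µm

    @property
    def linear_overlap(self) -> float:
        """Fractional overlap of adjacent VOI diameters along a grid axis."""
        return (2.0 * self.radius - self.spacing) / (2.0 * self.radius)


@dataclass
class FabricSample:
    centre: np.ndarray  # world point, µm
    eigenvalues: np.ndarray  # descending, trace 1 (zeros when undefined)
    axis: np.ndarray  # unit principal material direction (sign-free)
    da: float  # degree of anisotropy; 0 is the undefined sentinel
    n_normals: int
    degenerate_flag: bool = False

    @property
    def defined(self) -> bool:
        return self.n_normals > 0 and self.eigenvalues[0] > 0


@dataclass
class AnisotropyField:
    lattice: SamplingLattice
    samples: list[FabricSample]

    def defined_samples(self) -> list[FabricSample]:
        return [s for s in self.samples if s.defined]

    def da_values(self, include_sentinel: bool = False) -> np.ndarray:
        if include_sentinel:
            return np.array([s.da for s in self.samples])
        return np.array([s.da for s in self.defined_samples()])


@dataclass
class DAHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    mode: float | None  # Ani.M: centre of the max-count bin; None when empty

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())


@dataclass
class CoherenceSummary:
    region: str
    coherence: float | None  # None when under-populated
    n_samples: int


def lattice_spacing_rule(tb_th_um: float, default_um: float = DEFAULT_SPACING_UM) -> float:
    """VOI pitch: 500 µm, or 3x the mean trabecular width when that width
    exceeds the 167 µm changeover (the width at which 3x Tb.Th = 500 µm)."""
    if tb_th_um <= 0:
        raise ValueError("trabecular width must be positive")
    if 3.0 * tb_th_um > default_um:
        return 3.0 * tb_th_um
    return default_um


def build_lattice(
    trabecular_roi: LabelVolume,
    tb_th_um: float,
    spacing_um: float | None = None,
) -> SamplingLattice:
    """Place spherical VOI centres on a cubic grid over the trabecular ROI.

    Pitch follows :func:`lattice_spacing_rule` unless ``spacing_um``
    overrides it; radius of influence equals the pitch (50% overlap).
    The grid starts half a pitch inside the ROI bounding box and keeps
    only centres whose VOI intersects the ROI.
    """
    roi = trabecular_roi.labels == LABEL_TRABECULAR
    if not roi.any():
        raise ValueError("empty trabecular ROI")
    s = float(spacing_um) if spacing_um is not None else lattice_spacing_rule(tb_th_um)
    r = s
    sp = trabecular_roi.spacing
    origin = trabecular_roi.origin
    idx = np.argwhere(roi)
    lo_w = origin + idx.min(axis=0) * sp
    hi_w = origin + idx.max(axis=0) * sp
    axes = [
        np.arange(lo_w[a] + s / 2.0, hi_w[a] + 1e-9, s) for a in range(3)
    ]
    if any(len(a) == 0 for a in axes):
        axes = [a if len(a) else np.array([(l + h) / 2]) for a, l, h in zip(axes, lo_w, hi_w)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    # keep centres whose radius-r ball intersects the ROI: distance from the
    # centre to the nearest ROI voxel <= r (computed on the voxel grid)
    dist_vox = ndimage.distance_transform_edt(~roi, sampling=sp)
    keep = []
    for c in grid:
        ijk = np.round((c - origin) / sp).astype(int)
        ijk = np.clip(ijk, 0, np.array(roi.shape) - 1)
        if dist_vox[tuple(ijk)] <= r:
            keep.append(c)
    return SamplingLattice(spacing=s, radius=r, centres=np.asarray(keep).reshape(-1, 3))


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Bone voxels with at least one 6-connected background neighbour."""
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return mask & ~eroded


def surface_normals(
    mask: np.ndarray,
    spacing_um: float,
    smooth_sigma: float = 1.0,
    ball_centre: np.ndarray | None = None,
    ball_radius_um: float | None = None,
    _precomputed: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Unit outward surface normals of a binary structure.

    Normals are the normalised gradient of the Gaussian-smoothed (sigma 1
    voxel) mask, evaluated at surface voxels (bone voxels with a
    6-connected background neighbour).  When a ball is given, only
    surface voxels inside it contribute.  Returns an (n, 3) array; empty
    when the structure has no surface in the ball.
    """
    if _precomputed is not None:
        surf_idx, normals = _precomputed
    else:
        surf_idx, normals = precompute_surface_normals(mask, smooth_sigma)
    if ball_centre is not None:
        d2 = np.sum((surf_idx * spacing_um - ball_centre) ** 2, axis=1)
        keep = d2 <= (ball_radius_um or 0.0) ** 2
        return normals[keep]
    return normals


def precompute_surface_normals(
    mask: np.ndarray, smooth_sigma: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Surface voxel indices and their unit normals for a whole mask."""
    mask = np.asarray(mask, dtype=bool)
    surf = _surface_voxels(mask)
    surf_idx = np.argwhere(surf)
    if surf_idx.size == 0:
        return surf_idx.reshape(0, 3), np.zeros((0, 3))
    smoothed = ndimage.gaussian_filter(mask.astype(np.float32), smooth_sigma)
    grads = np.stack(np.gradient(smoothed), axis=-1)
    g = grads[surf]
    mag = np.linalg.norm(g, axis=1)
    ok = mag >= 1e-6
    normals = -g[ok] / mag[ok, None]  # gradient points inward (low→high); flip
    return surf_idx[ok], normals


def fabric_tensor(
    normals: np.ndarray,
    min_count: int = DEFAULT_MIN_NORMALS,
    long_axis: int = 2,
    degeneracy_tol: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Eigen-analysis of the normal orientation tensor.

    Returns ``(eigenvalues_desc, axis, da, degenerate_flag)``.  With fewer
    than ``min_count`` normals the sample is undefined: eigenvalues are
    zero and ``da`` is the sentinel 0.  The axis is sign-free and is
    reported with a non-negative component along ``long_axis``.
    """
    normals = np.asarray(normals, dtype=float).reshape(-1, 3)
    if len(normals) < min_count:
        return np.zeros(3), np.zeros(3), 0.0, False
    C = normals.T @ normals / len(normals)
    C /= np.trace(C)
    evals, evecs = np.linalg.eigh(C)  # ascending
    evals_desc = evals[::-1]
    lam_max, lam_min = evals_desc[0], evals_desc[2]
    da = float(1.0 - lam_min / lam_max) if lam_max > 0 else 0.0
    axis = evecs[:, 0]  # eigenvector of the smallest eigenvalue
    if axis[long_axis] < 0:
        axis = -axis
    degenerate = bool((evals_desc[1] - evals_desc[2]) / lam_max < degeneracy_tol)
    return evals_desc, axis, da, degenerate


def map_anisotropy(
    label: LabelVolume,
    lattice: SamplingLattice,
    min_normals: int = DEFAULT_MIN_NORMALS,
    smooth_sigma: float = 1.0,
) -> AnisotropyField:
    """Fabric sample at every lattice VOI over the trabecular compartment.

    VOIs whose ball collects fewer than ``min_normals`` trabecular surface
    normals (e.g. balls lying in open cavity) produce the DA = 0 sentinel.
    """
    roi = label.labels == LABEL_TRABECULAR
    sp = float(label.spacing[0])
    surf_idx, normals = precompute_surface_normals(roi, smooth_sigma)
    surf_world = surf_idx * sp + label.origin
    samples: list[FabricSample] = []
    r2 = lattice.radius**2
    for c in lattice.centres:
        if len(surf_world):
            d2 = np.sum((surf_world - c) ** 2, axis=1)
            local = normals[d2 <= r2]
        else:
            local = np.zeros((0, 3))
        evals, axis, da, degen = fabric_tensor(local, min_count=min_normals)
        samples.append(
            FabricSample(
                centre=np.asarray(c, dtype=float),
                eigenvalues=evals,
                axis=axis,
                da=da,
                n_normals=len(local),
                degenerate_flag=degen,
            )
        )
    return AnisotropyField(lattice=lattice, samples=samples)


def da_histogram(field: AnisotropyField, bin_width: float = 0.05) -> DAHistogram:
    """Zero-excluded DA histogram over [0, 1] and its modal bin (Ani.M).

    Undefined (sentinel 0) samples are discarded before binning; ties at
    the maximum count break to the lower bin.
    """
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    da = field.da_values(include_sentinel=False)
    da = da[da > 0]
    counts, _ = np.histogram(da, bins=edges)
    if counts.sum() == 0:
        return DAHistogram(bin_edges=edges, counts=counts, mode=None)
    imax = int(np.argmax(counts))  # argmax takes the first (lower) max bin
    mode = float(0.5 * (edges[imax] + edges[imax + 1]))
    return DAHistogram(bin_edges=edges, counts=counts, mode=mode)


def filter_high(field: AnisotropyField, threshold: float = DEFAULT_HIGH_DA) -> AnisotropyField:
    """Subset of samples with DA at or above the threshold (default 0.65)."""
    kept = [s for s in field.samples if s.defined and s.da >= threshold]
    return AnisotropyField(lattice=field.lattice, samples=kept)


def _axial_coherence(axes: np.ndarray) -> float:
    """(3*eta1 - 1)/2 for eta1 the top eigenvalue of the mean outer product.

    0 for axes uniform over the sphere, 1 for identical axes; sign-free.
    """
    axes = np.asarray(axes, dtype=float).reshape(-1, 3)
    axes = axes / np.linalg.norm(axes, axis=1, keepdims=True)
    T = axes.T @ axes / len(axes)
    eta1 = float(np.linalg.eigvalsh(T)[-1])
    return (3.0 * eta1 - 1.0) / 2.0


def coherence(
    field: AnisotropyField,
    long_axis: int = 2,
    n_regions: int = 3,
    min_samples: int = 5,
) -> list[CoherenceSummary]:
    """Axial alignment of sample axes within thirds along the long axis.

    Quantifies "aligned regions of high anisotropy": feed it the
    :func:`filter_high` subset.  Regions with fewer than ``min_samples``
    samples are reported with ``coherence=None``.
    """
    names = {3: ["proximal", "mid", "distal"]}.get(
        n_regions, [f"region{i}" for i in range(n_regions)]
    )
    samples = field.defined_samples()
    if not samples:
        return [CoherenceSummary(region=nm, coherence=None, n_samples=0) for nm in names]
    z = np.array([s.centre[long_axis] for s in samples])
    lo, hi = z.min(), z.max()
    edges = np.linspace(lo, hi + 1e-9, n_regions + 1)
    out = []
    for i, nm in enumerate(names):
        sel = [s for s, zz in zip(samples, z) if edges[i] <= zz < edges[i + 1]]
        if len(sel) < min_samples:
            out.append(CoherenceSummary(region=nm, coherence=None, n_samples=len(sel)))
        else:
            axes = np.array([s.axis for s in sel])
            out.append(
                CoherenceSummary(
                    region=nm, coherence=_axial_coherence(axes), n_samples=len(sel)
                )
            )
    return out


# ---------------------------------------------------------------------------
# mean-intercept-length oracle


def _fibonacci_directions(n: int) -> np.ndarray:
    """Quasi-uniform directions on the hemisphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5**0.5) * i
    z = i / n  # upper hemisphere suffices: MIL is antipodally symmetric
    r = np.sqrt(1 - z**2)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def mil_fabric(
    mask: np.ndarray,
    spacing_um: float = 1.0,
    n_directions: int = 128,
    long_axis: int = 2,
    step_vox: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Mean-intercept-length fabric of a binary structure.

    For each direction, parallel probe lines are marched through the
    mask's bounding box; MIL(direction) = total bone length / number of
    bone-entry crossings.  The MIL ellipsoid is fitted by least squares
    on ``1 / MIL**2`` and eigen-analysed; the material axis is the
    *longest* MIL axis (smallest ellipsoid eigenvalue) and
    ``da = 1 - MIL_min / MIL_max``.  Slow and simple on purpose: this is
    the in-repo oracle for the surface-normal estimator.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    shape = np.array(mask.shape)
    dirs = _fibonacci_directions(n_directions)
    centre = (shape - 1) / 2.0
    diag = float(np.linalg.norm(shape))
    n_t = int(diag / step_vox) + 1
    t = (np.arange(n_t) - n_t // 2) * step_vox
    mils = []
    used_dirs = []
    rng = np.random.default_rng(0)  # fixed probe offsets: deterministic oracle
    for d in dirs:
        # build a bundle of parallel lines: offsets on the plane normal to d
        e1 = np.cross(d, [1.0, 0.0, 0.0])
        if np.linalg.norm(e1) < 1e-6:
            e1 = np.cross(d, [0.0, 1.0, 0.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d, e1)
        max_off = shape.max() / 2.0
        # stratified probe bundle: regular offset grid with a small jitter
        side = 10
        g = (np.arange(side) + 0.5) / side * 2.0 - 1.0
        gu, gv = np.meshgrid(g, g, indexing="ij")
        offs = np.stack([gu.ravel(), gv.ravel()], axis=1) * max_off
        offs += rng.uniform(-0.5, 0.5, size=offs.shape) * (2 * max_off / side) * 0.5
        # all probe points of the bundle at once: (n_lines, n_t, 3)
        pts = (
            centre
            + offs[:, 0, None, None] * e1
            + offs[:, 1, None, None] * e2
            + t[None, :, None] * d
        )
        ijk = np.round(pts).astype(int)
        inside = np.all((ijk >= 0) & (ijk < shape), axis=2)
        vals = np.zeros(inside.shape, dtype=bool)
        ii = ijk[inside]
        vals[inside] = mask[ii[:, 0], ii[:, 1], ii[:, 2]]
        bone_len = float(vals.sum()) * step_vox
        crossings = int(np.count_nonzero(np.diff(vals.astype(np.int8), axis=1) == 1))
        if crossings > 0:
            mils.append(bone_len / crossings)
            used_dirs.append(d)
    if len(used_dirs) < 9:
        raise ValueError("too few usable probe directions for the MIL fit")
    mils = np.asarray(mils) * spacing_um
    dirs_used = np.asarray(used_dirs)
    # fit 1/MIL^2 = n^T H n for symmetric H
    n1, n2, n3 = dirs_used.T
    design = np.stack(
        [n1 * n1, n2 * n2, n3 * n3, 2 * n1 * n2, 2 * n1 * n3, 2 * n2 * n3], axis=1
    )
    target = 1.0 / mils**2
    h, *_ = np.linalg.lstsq(design, target, rcond=None)
    H = np.array(
        [[h[0], h[3], h[4]], [h[3], h[1], h[5]], [h[4], h[5], h[2]]]
    )
    evals, evecs = np.linalg.eigh(H)  # ascending; MIL_axis ~ 1/sqrt(eval)
    evals = np.clip(evals, 1e-12, None)
    mil_lengths = 1.0 / np.sqrt(evals)  # descending MIL
    da = float(1.0 - mil_lengths[2] / mil_lengths[0])
    axis = evecs[:, 0]  # longest MIL direction
    if axis[long_axis] < 0:
        axis = -axis
    return mil_lengths, axis, da
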