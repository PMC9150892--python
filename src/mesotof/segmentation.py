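"""Semi-automatic vessel segmentation.

Pipeline: homomorphic bias normalization, global primary threshold with
small-cluster removal, iterative region growing down to a secondary
threshold, then FRE measurement against a one-voxel rim, skeleton-length
quantification and maximum intensity projections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .io import Volume

__all__ = [
    "SegmentationConfig",
    "SegmentationResult",
    "bias_normalize",
    "initial_mask",
    "region_grow",
    "measure_fre",
    "skeleton_length_mm",
    "mip",
    "segment_volume",
    "dice",
]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def _structure(connectivity: int) -> np.ndarray:
    try:
        return _STRUCTURES[connectivity]
    except KeyError:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds and morphology settings.

    ``min_cluster_voxels`` follows the "clusters with fewer than N voxels
    are removed" rule: a cluster of exactly N voxels is retained.
    Defaults 10 (high-res) / 5 (low-res) are the published choices; the
    thresholds themselves are data-dependent and must be supplied.
    """

    primary_threshold: float
    secondary_threshold: float
    min_cluster_voxels: int = 10
    connectivity: int = 26
    bias_sigma_mm: float = 4.0

    def __post_init__(self):
        if self.secondary_threshold > self.primary_threshold:
            raise ValueError("secondary_threshold must be <= primary_threshold")
        if self.min_cluster_voxels < 1:
            raise ValueError("min_cluster_voxels must be >= 1")
        _structure(self.connectivity)
        if self.bias_sigma_mm <= 0:
            raise ValueError("bias_sigma_mm must be positive")


@dataclass
class SegmentationResult:
    vessel_mask: Volume
    components: Volume                       # int labels, 0 = background
    component_sizes: dict = field(default_factory=dict)  # label -> voxel count
    skeleton: Volume | None = None
    skeleton_length_mm: float = 0.0


def bias_normalize(vol: Volume, sigma_mm: float) -> Volume:
    """Homomorphic normalization: divide by a Gaussian-smoothed copy.

    The smoothed divisor is floor-clamped at a small fraction of its own
    maximum to avoid division blow-up in dark regions, and the output is
    rescaled so its global median equals the input's.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be positive")
    data = np.asarray(vol.data, dtype=float)
    if not np.any(data):
        raise ValueError("cannot normalize an all-zero volume")
    sigma_vox = sigma_mm / vol.voxel_mm
    smooth = ndimage.gaussian_filter(data, sigma=sigma_vox, mode="nearest")
    floor = 1e-3 * smooth.max()
    ratio = data / np.maximum(smooth, floor)
    med_in = np.median(data)
    med_ratio = np.median(ratio)
    if med_ratio == 0:
        raise ValueError("degenerate volume: zero median after normalization")
    return vol.like(ratio * (med_in / med_ratio))


def initial_mask(vol: Volume, primary_threshold: float,
                 min_cluster_voxels: int = 10, connectivity: int = 26) -> Volume:
    """Threshold, then drop connected clusters with fewer than N voxels."""
    structure = _structure(connectivity)
    raw = vol.data > primary_threshold
    labels, n = ndimage.label(raw, structure=structure)
    if n:
        sizes = np.bincount(labels.ravel())
        small = sizes < min_cluster_voxels
        small[0] = False
        raw[small[labels]] = False
    return vol.like(raw.astype(np.uint8))


def region_grow(vol: Volume, seed_mask: Volume, secondary_threshold: float,
                connectivity: int = 26) -> Volume:
    """Fixed point of adding connected voxels above the secondary threshold.

    Equivalent to keeping every connected component of the
    above-secondary set that touches the seed mask, unioned with the
    seeds; independent of seed processing order and idempotent.
    """
    if seed_mask.shape != vol.shape:
        raise ValueError("seed mask grid mismatch")
    structure = _structure(connectivity)
    seeds = seed_mask.data.astype(bool)
    if not seeds.any():
        return vol.like(np.zeros(vol.shape, dtype=np.uint8))
    candidates = vol.data > secondary_threshold
    labels, n = ndimage.label(candidates, structure=structure)
    keep = np.unique(labels[seeds & candidates])
    keep = keep[keep > 0]
    grown = np.isin(labels, keep) | seeds
    return vol.like(grown.astype(np.uint8))


def measure_fre(vol: Volume, vessel_mask: Volume) -> float:
    """Relative FRE of a mask: (mean inside - mean rim) / mean rim.

    The tissue reference is the 1-voxel rim, i.e. the 26-connected
    dilation of the mask minus the mask itself.
    """
    if vessel_mask.shape != vol.shape:
        raise ValueError("mask grid mismatch")
    mask = vessel_mask.data.astype(bool)
    if not mask.any():
        raise ValueError("empty vessel mask")
    rim = ndimage.binary_dilation(mask, structure=_STRUCTURES[26]) & ~mask
    if not rim.any():
        raise ValueError("empty rim: mask fills the volume")
    mean_in = float(vol.data[mask].mean())
    mean_rim = float(vol.data[rim].mean())
    if mean_rim == 0:
        raise ValueError("zero tissue reference in rim")
    return (mean_in - mean_rim) / mean_rim


def skeleton_length_mm(mask: Volume, voxel_mm: float | None = None,
                       from_mip_axis: int | None = None) -> float:
    """Skeletonize and report (voxel count) x (voxel size) in mm.

    With ``from_mip_axis`` set, the mask is first collapsed by maximum
    projection along that axis and a 2D skeleton is measured instead.
    """
    if voxel_mm is None:
        mask.require_isotropic("skeleton length")
        voxel_mm = float(mask.voxel_mm[0])
    data = mask.data.astype(bool)
    if from_mip_axis is not None:
        data = data.max(axis=from_mip_axis)
    if not data.any():
        return 0.0
    skel = skeletonize(data)
    return float(skel.sum()) * voxel_mm


def mip(vol: Volume, axis: int, slab_range: tuple | None = None) -> np.ndarray:
    """Maximum intensity projection over a slab of slices along an axis."""
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    n = vol.shape[axis]
    lo, hi = (0, n) if slab_range is None else slab_range
    if not (0 <= lo < hi <= n):
        raise ValueError(f"slab range ({lo}, {hi}) outside volume extent {n}")
    sl = [slice(None)] * 3
    sl[axis] = slice(lo, hi)
    return np.asarray(vol.data[tuple(sl)].max(axis=axis))


def segment_volume(vol: Volume, cfg: SegmentationConfig,
                   brain_mask: Volume | None = None,
                   normalize: bool = True,
                   denoise=None) -> SegmentationResult:
    """Full pipeline: normalize -> threshold + declutter -> region grow.

    ``denoise`` is an optional hook (callable Volume -> Volume); by
    default no denoising is applied. Returns a SegmentationResult with
    labelled components, per-component sizes, skeleton and its length.
    """
    work = bias_normalize(vol, cfg.bias_sigma_mm) if normalize else vol
    if denoise is not None:
        work = denoise(work)
    if brain_mask is not None:
        if brain_mask.shape != work.shape:
            raise ValueError("brain mask grid mismatch")
        work = work.like(work.data * brain_mask.data.astype(bool))
    seeds = initial_mask(work, cfg.primary_threshold, cfg.min_cluster_voxels,
                         cfg.connectivity)
    grown = region_grow(work, seeds, cfg.secondary_threshold, cfg.connectivity)
    labels, n = ndimage.label(grown.data.astype(bool),
                              structure=_structure(cfg.connectivity))
    sizes = {int(lab): int(cnt) for lab, cnt in
             zip(*np.unique(labels[labels > 0], return_counts=True))}
    skel_data = (skeletonize(grown.data.astype(bool))
                 if grown.data.any() else np.zeros(grown.shape, dtype=bool))
    length = (float(skel_data.sum()) * float(vol.voxel_mm[0])
              if vol.is_isotropic else float("nan"))
    return SegmentationResult(
        vessel_mask=grown,
        components=vol.like(labels.astype(np.int32)),
        component_sizes=sizes,
        skeleton=vol.like(skel_data.astype(np.uint8)),
        skeleton_length_mm=length,
    )


def dice(mask_a: Volume, mask_b: Volume) -> float:
    """Dice overlap of two binary masks."""
    a = mask_a.data.astype(bool)
    b = mask_b.data.astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
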