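"""Two-echo T2* estimation and per-component vein removal.

T2* is estimated voxelwise from the natural logarithm of the intensity
ratio of two echoes and the echo-time difference. Connected vessel
components whose 90th-percentile T2* falls below a threshold are
classified as veins and removed; veins have much shorter T2* than
arteries, whose T2* is close to that of tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import Volume
from .segmentation import SegmentationResult

__all__ = [
    "T2StarMap",
    "t2star_map",
    "component_t2star_p90",
    "remove_veins",
    "resample_mask_nearest",
    "flag_components_by_overlap",
]


@dataclass
class T2StarMap:
    """Voxelwise T2* (ms) with a flag where the two-point estimate degenerates."""

    values: Volume
    clamped: Volume          # 1 where S2 >= S1 or non-positive intensities
    delta_te_ms: float
    clamp_ms: float = 1000.0

    def __post_init__(self):
        if self.delta_te_ms <= 0:
            raise ValueError("delta_te_ms must be positive")


def t2star_map(echo1: Volume, echo2: Volume, delta_te_ms: float,
               clamp_ms: float = 1000.0) -> T2StarMap:
    """Two-point mono-exponential T2*: dTE / ln(S1/S2).

    Valid where S1 > S2 > 0; everywhere else the estimate is clamped to
    ``clamp_ms`` and flagged (noise can make S2 >= S1).
    """
    if echo1.shape != echo2.shape:
        raise ValueError(f"echo grids differ: {echo1.shape} vs {echo2.shape}")
    if delta_te_ms <= 0:
        raise ValueError("delta_te_ms must be positive")
    s1 = np.asarray(echo1.data, dtype=float)
    s2 = np.asarray(echo2.data, dtype=float)
    bad = ~((s1 > 0) & (s2 > 0) & (s1 > s2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = delta_te_ms / np.log(s1 / s2)
    t2 = np.where(bad, clamp_ms, t2)
    return T2StarMap(
        values=echo1.like(t2),
        clamped=echo1.like(bad.astype(np.uint8)),
        delta_te_ms=delta_te_ms,
        clamp_ms=clamp_ms,
    )


def component_t2star_p90(t2map: T2StarMap, components: Volume,
                         percentile: float = 90.0,
                         interpolation: str = "linear") -> dict:
    """Per-component percentile of unclamped T2* values.

    Returns {label: percentile_ms or None}; ``None`` marks components
    containing only clamped voxels (retained as arterial by default
    downstream). Linear interpolation is the default convention.
    """
    labels = components.data.astype(np.int64)
    out: dict[int, float | None] = {}
    ok = ~t2map.clamped.data.astype(bool)
    for lab in np.unique(labels[labels > 0]):
        vals = t2map.values.data[(labels == lab) & ok]
        out[int(lab)] = (float(np.percentile(vals, percentile,
                                             method=interpolation))
                         if vals.size else None)
    return out


def remove_veins(seg: SegmentationResult, t2map: T2StarMap,
                 threshold_ms: float, percentile: float = 90.0) -> tuple:
    """Drop components whose p90 T2* is below the threshold.

    Returns (filtered SegmentationResult, venous-only mask Volume,
    decision table {label: (p90_or_None, is_vein)}). Components with only
    clamped voxels are retained. Monotone in the threshold: a larger
    threshold removes a superset of components.
    """
    if threshold_ms < 0:
        raise ValueError("threshold_ms must be >= 0")
    p90 = component_t2star_p90(t2map, seg.components, percentile=percentile)
    vein_labels = [lab for lab, v in p90.items()
                   if v is not None and v < threshold_ms]
    labels = seg.components.data.astype(np.int64)
    vein_mask = np.isin(labels, vein_labels)
    kept = seg.vessel_mask.data.astype(bool) & ~vein_mask

    kept_labels = np.where(vein_mask, 0, labels)
    sizes = {lab: n for lab, n in seg.component_sizes.items()
             if lab not in vein_labels}
    from skimage.morphology import skeletonize

    skel = (skeletonize(kept) if kept.any()
            else np.zeros(kept.shape, dtype=bool))
    vol0 = seg.vessel_mask
    filtered = SegmentationResult(
        vessel_mask=vol0.like(kept.astype(np.uint8)),
        components=vol0.like(kept_labels.astype(np.int32)),
        component_sizes=sizes,
        skeleton=vol0.like(skel.astype(np.uint8)),
        skeleton_length_mm=(float(skel.sum()) * float(vol0.voxel_mm[0])
                            if vol0.is_isotropic else float("nan")),
    )
    decisions = {lab: (v, lab in vein_labels) for lab, v in p90.items()}
    return filtered, vol0.like(vein_mask.astype(np.uint8)), decisions


def resample_mask_nearest(mask: Volume, target: Volume) -> Volume:
    """Nearest-neighbour resampling of a binary mask onto a target grid.

    Maps target voxel centres through both affines (world mm); voxels
    landing outside the source grid are background.
    """
    src = mask.data
    inv = np.linalg.inv(mask.affine)
    ti, tj, tk = np.meshgrid(*(np.arange(s) for s in target.shape),
                             indexing="ij")
    coords = np.stack([ti, tj, tk, np.ones_like(ti)], axis=-1).reshape(-1, 4)
    world = coords @ target.affine.T
    src_idx = np.round(world @ inv.T)[:, :3].astype(int)
    ok = np.all((src_idx >= 0) & (src_idx < np.array(src.shape)), axis=1)
    out = np.zeros(np.prod(target.shape), dtype=src.dtype)
    out[ok] = src[tuple(src_idx[ok].T)]
    return target.like(out.reshape(target.shape))


def flag_components_by_overlap(components: Volume, vein_mask_lowres: Volume,
                               min_overlap: float = 0.5) -> list:
    """Labels of components mostly covered by a (resampled) venous mask.

    Used for low-resolution-guided vein removal: a component is flagged
    venous when at least ``min_overlap`` of its voxels fall inside the
    resampled low-resolution vein mask.
    """
    vein = resample_mask_nearest(vein_mask_lowres, components).data.astype(bool)
    labels = components.data.astype(np.int64)
    flagged = []
    for lab in np.unique(labels[labels > 0]):
        sel = labels == lab
        if vein[sel].mean() >= min_overlap:
            flagged.append(int(lab))
    return flagged
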