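"""Synthetic 3D angiogram phantom.

Generates sparse branching vessel trees (side branches leave the parent
at a near-right angle with reduced diameter), rasterizes them into
blood-volume-fraction maps by supersampled point-in-cylinder counting,
simulates spoiled-GRE inflow intensities with per-compartment T2*
weighting (arteries close to tissue, veins markedly shorter), and adds
Rician noise and a smooth multiplicative bias field. Every map needed as
ground truth downstream (fraction, delivery time, artery/vein labels,
binary vessel mask) is produced alongside the images.

All stochastic operations are reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import Volume
from .partial_volume import blood_fraction
from .signal_model import AcquisitionParams, TissueParams, _inflow_mz_n, n_rf_pulses, steady_state_mz

__all__ = [
    "VesselSegment",
    "VesselTree",
    "PhantomConfig",
    "RasterResult",
    "generate_tree",
    "merge_trees",
    "rasterize_fraction_map",
    "simulate_tof",
    "add_rician_noise",
    "add_bias_field",
    "generate_phantom",
]

LABEL_TISSUE, LABEL_ARTERY, LABEL_VEIN = 0, 1, 2
_KIND_LABEL = {"artery": LABEL_ARTERY, "vein": LABEL_VEIN}


@dataclass
class VesselSegment:
    """One straight cylindrical vessel piece."""

    start_mm: np.ndarray
    end_mm: np.ndarray
    diameter_mm: float
    velocity_mm_s: float
    delivery_offset_ms: float
    kind: str = "artery"
    parent_index: int | None = None
    branch_angle_deg: float | None = None  # set on side branches only

    def __post_init__(self):
        self.start_mm = np.asarray(self.start_mm, dtype=float)
        self.end_mm = np.asarray(self.end_mm, dtype=float)
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be positive")
        if self.delivery_offset_ms < 0:
            raise ValueError("delivery_offset_ms must be >= 0")
        if self.kind not in _KIND_LABEL:
            raise ValueError(f"kind must be artery|vein, got {self.kind!r}")
        if self.length_mm <= 0:
            raise ValueError("segment must have nonzero length")

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(self.end_mm - self.start_mm))

    @property
    def transit_ms(self) -> float:
        return 1000.0 * self.length_mm / self.velocity_mm_s

    @property
    def direction(self) -> np.ndarray:
        return (self.end_mm - self.start_mm) / self.length_mm


@dataclass
class VesselTree:
    """Connected collection of segments rooted on a slab face."""

    segments: list
    rng_seed: int = 0

    def __post_init__(self):
        for seg in self.segments:
            if seg.parent_index is not None:
                parent = self.segments[seg.parent_index]
                if seg.diameter_mm > parent.diameter_mm + 1e-9:
                    raise ValueError("child diameter exceeds parent diameter")
                if seg.delivery_offset_ms < parent.delivery_offset_ms - 1e-9:
                    raise ValueError("delivery offset must not decrease root->leaf")


@dataclass(frozen=True)
class PhantomConfig:
    fov_mm: tuple = (19.2, 19.2, 19.2)
    voxel_mm: float = 0.3
    supersampling_factor: int = 7
    n_trees: int = 2
    n_vein_trees: int = 1
    depth: int = 3
    root_diameter_mm: float = 0.9
    diameter_range_mm: tuple = (0.05, 0.9)
    velocity_range_mm_s: tuple = (10.0, 50.0)
    taper: float = 0.8               # side-branch diameter ratio
    continuation_taper: float = 0.95  # along-vessel diameter ratio
    branch_angle_deg: float = 90.0
    branch_angle_jitter_deg: float = 15.0
    segment_length_mm: tuple = (2.0, 4.0)
    root_delivery_ms: float = 200.0
    vein_delivery_ms: float = 3000.0  # saturated unless pass-through
    noise_sigma: float = 0.0
    bias_amplitude: float = 0.0
    bias_scale_mm: float = 8.0

    def __post_init__(self):
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")
        if self.supersampling_factor < 3 or self.supersampling_factor % 2 == 0:
            raise ValueError("supersampling_factor must be odd and >= 3")
        if any(f <= 0 for f in self.fov_mm):
            raise ValueError(f"degenerate FOV {self.fov_mm}")
        if not (0 < self.taper <= 1 and 0 < self.continuation_taper <= 1):
            raise ValueError("tapers must be in (0, 1]")

    @property
    def grid_shape(self) -> tuple:
        shape = tuple(int(round(f / self.voxel_mm)) for f in self.fov_mm)
        if any(s < 1 for s in shape):
            raise ValueError("FOV smaller than one voxel")
        return shape


def _velocity_for_diameter(d_mm: float, cfg: PhantomConfig) -> float:
    """Monotone linear diameter -> velocity map (configurable, not a claim)."""
    d_lo, d_hi = cfg.diameter_range_mm
    v_lo, v_hi = cfg.velocity_range_mm_s
    t = np.clip((d_mm - d_lo) / (d_hi - d_lo), 0.0, 1.0)
    return float(v_lo + t * (v_hi - v_lo))


def _perpendicular(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random unit vector orthogonal to u."""
    while True:
        w = rng.normal(size=3)
        w -= np.dot(w, u) * u
        n = np.linalg.norm(w)
        if n > 1e-6:
            return w / n


def _rotate_towards(u, w, angle_rad):
    return np.cos(angle_rad) * u + np.sin(angle_rad) * w


def generate_tree(cfg: PhantomConfig, rng_seed: int, kind: str = "artery",
                  root_delivery_ms: float | None = None) -> VesselTree:
    """Grow a binary-branching vessel tree inside the FOV.

    The root enters on the x = 0 face heading into the slab. At every
    branch point one child continues the parent vessel (slightly jittered
    direction, diameter x continuation_taper) and one side branch leaves
    at ``branch_angle_deg`` +/- jitter with diameter x taper. Velocity is
    a monotone function of diameter; the cumulative delivery time grows
    by the parent's transit time at each generation.
    """
    rng = np.random.default_rng(rng_seed)
    fov = np.asarray(cfg.fov_mm, dtype=float)
    margin = cfg.root_diameter_mm
    if root_delivery_ms is None:
        root_delivery_ms = (cfg.root_delivery_ms if kind == "artery"
                            else cfg.vein_delivery_ms)

    segments: list[VesselSegment] = []

    def clamp_end(start, direction, length):
        end = start + direction * length
        end = np.clip(end, margin, fov - margin)
        return end

    def grow(start, direction, diameter, delivery, depth, parent_index,
             branch_angle=None):
        length = rng.uniform(*cfg.segment_length_mm)
        end = clamp_end(start, direction, length)
        if np.linalg.norm(end - start) < 0.2:
            return
        seg = VesselSegment(
            start_mm=start, end_mm=end, diameter_mm=diameter,
            velocity_mm_s=_velocity_for_diameter(diameter, cfg),
            delivery_offset_ms=delivery, kind=kind,
            parent_index=parent_index, branch_angle_deg=branch_angle)
        segments.append(seg)
        idx = len(segments) - 1
        if depth <= 0:
            return
        child_delivery = delivery + seg.transit_ms
        u = seg.direction
        # continuation: small jitter around the parent direction
        jitter = np.deg2rad(rng.uniform(0.0, 10.0))
        cont_dir = _rotate_towards(u, _perpendicular(u, rng), jitter)
        grow(end, cont_dir, diameter * cfg.continuation_taper, child_delivery,
             depth - 1, idx)
        # side branch near a right angle, significantly reduced diameter
        angle = rng.uniform(cfg.branch_angle_deg - cfg.branch_angle_jitter_deg,
                            cfg.branch_angle_deg + cfg.branch_angle_jitter_deg)
        side_dir = _rotate_towards(u, _perpendicular(u, rng), np.deg2rad(angle))
        d_side = max(diameter * cfg.taper, cfg.diameter_range_mm[0])
        d_side = min(d_side, diameter)
        grow(end, side_dir, d_side, child_delivery, depth - 1, idx,
             branch_angle=angle)

    entry = np.array([margin,
                      rng.uniform(0.3 * fov[1], 0.7 * fov[1]),
                      rng.uniform(0.3 * fov[2], 0.7 * fov[2])])
    direction = np.array([1.0, 0.0, 0.0])
    direction = _rotate_towards(direction, _perpendicular(direction, rng),
                                np.deg2rad(rng.uniform(0.0, 10.0)))
    grow(entry, direction, cfg.root_diameter_mm, float(root_delivery_ms),
         cfg.depth, None)
    return VesselTree(segments=segments, rng_seed=rng_seed)


def merge_trees(trees) -> VesselTree:
    """Concatenate several trees into one segment list (indices re-based)."""
    segments = []
    for tree in trees:
        offset = len(segments)
        for seg in tree.segments:
            seg = replace(seg, parent_index=(None if seg.parent_index is None
                                             else seg.parent_index + offset))
            segments.append(seg)
    return VesselTree(segments=segments,
                      rng_seed=trees[0].rng_seed if trees else 0)


@dataclass
class RasterResult:
    """Ground-truth maps emitted by the rasterizer."""

    fraction: Volume   # blood volume fraction in [0, 1]
    delivery: Volume   # blood delivery time (ms), 0 outside vessels
    labels: Volume     # 0 tissue, 1 artery, 2 vein
    mask: Volume       # binary ground-truth vessel mask


def rasterize_fraction_map(tree: VesselTree, cfg: PhantomConfig) -> RasterResult:
    """Supersampled rasterization of a vessel tree.

    Per voxel, the blood fraction is the share of s^3 subsample points
    (s = supersampling_factor, point offsets at subcell centres) falling
    inside any finite cylinder. Overlapping segments combine by maximum.
    The delivery map takes, at each vessel voxel, the nearest segment
    axis point (ties to the smaller segment index) and adds the
    along-segment transit time. The ground-truth mask marks voxels whose
    per-segment fraction exceeds half the maximum attainable fraction for
    that segment's diameter at this voxel size.
    """
    l = cfg.voxel_mm
    shape = cfg.grid_shape
    s = cfg.supersampling_factor

    fraction = np.zeros(shape, dtype=np.float64)
    delivery = np.zeros(shape, dtype=np.float64)
    labels = np.zeros(shape, dtype=np.int16)
    mask = np.zeros(shape, dtype=bool)
    best_frac = np.zeros(shape, dtype=np.float64)
    best_dist = np.full(shape, np.inf, dtype=np.float64)

    # subcell-centre offsets within one voxel
    off1 = (np.arange(s) + 0.5) / s - 0.5
    ox, oy, oz = np.meshgrid(off1, off1, off1, indexing="ij")
    offsets = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1) * l

    for seg in tree.segments:
        r = seg.diameter_mm / 2.0
        lo = np.minimum(seg.start_mm, seg.end_mm) - r - l
        hi = np.maximum(seg.start_mm, seg.end_mm) + r + l
        i_lo = np.maximum(np.floor(lo / l).astype(int), 0)
        i_hi = np.minimum(np.ceil(hi / l).astype(int), shape)
        if np.any(i_lo >= i_hi):
            continue
        ii, jj, kk = np.meshgrid(*(np.arange(a, b) for a, b in zip(i_lo, i_hi)),
                                 indexing="ij")
        idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        centers = (idx + 0.5) * l

        u = seg.direction
        length = seg.length_mm
        h = l / s  # subcell edge; linear antialiasing width
        frac_seg = np.empty(len(centers), dtype=np.float64)
        chunk = 4096
        for c0 in range(0, len(centers), chunk):
            pts = centers[c0:c0 + chunk, None, :] + offsets[None, :, :]
            w = pts - seg.start_mm
            t = w @ u
            perp = w - t[..., None] * u
            radial = np.sqrt(np.einsum("ijk,ijk->ij", perp, perp))
            # subcell coverage: 1 well inside, 0 well outside, linear ramp
            # across one subcell at the cylinder wall and the end caps
            cov_r = np.clip(0.5 + (r - radial) / h, 0.0, 1.0)
            cov_a = np.clip(0.5 + np.minimum(t, length - t) / h, 0.0, 1.0)
            frac_seg[c0:c0 + chunk] = (cov_r * cov_a).mean(axis=1)

        sel = frac_seg > 0
        if not np.any(sel):
            continue
        flat = tuple(idx[sel].T)
        f = frac_seg[sel]

        fraction[flat] = np.maximum(fraction[flat], f)

        # delivery / label from the nearest segment axis (strict <: earlier
        # segment index wins ties)
        wc = centers[sel] - seg.start_mm
        tc = np.clip(wc @ u, 0.0, length)
        dist = np.linalg.norm(wc - tc[:, None] * u, axis=1)
        closer = dist < best_dist[flat]
        upd = tuple(c[closer] for c in flat)
        best_dist[upd] = dist[closer]
        delivery[upd] = (seg.delivery_offset_ms
                         + 1000.0 * tc[closer] / seg.velocity_mm_s)
        labels[upd] = _KIND_LABEL[seg.kind]

        better = f > best_frac[flat]
        best_frac[tuple(c[better] for c in flat)] = f[better]

        max_attainable = blood_fraction(seg.diameter_mm, l)
        mask[flat] |= f > 0.5 * max_attainable

    delivery[fraction == 0] = 0.0
    labels[fraction == 0] = LABEL_TISSUE

    vox = np.full(3, l)
    base = Volume(fraction, vox)
    return RasterResult(
        fraction=base,
        delivery=base.like(delivery),
        labels=base.like(labels),
        mask=base.like(mask.astype(np.uint8)),
    )


def simulate_tof(fraction: Volume, delivery: Volume, acq: AcquisitionParams,
                 tis: TissueParams, echo_index: int = 0,
                 labels: Volume | None = None) -> Volume:
    """Noiseless TOF image from fraction/delivery/label maps.

    Voxel signal is the volume-fraction-weighted sum of the inflowing
    blood and steady-state tissue magnetizations, each decayed with its
    own compartment T2* at the selected echo time:

        S = V * Mz_blood(t_delivery) * exp(-TE / T2*_kind)
          + (1 - V) * MzS_tissue * exp(-TE / T2*_tissue)

    with T2*_kind chosen per voxel from the artery/vein label map
    (arteries where no label map is given).
    """
    if fraction.shape != delivery.shape:
        raise ValueError(f"grid mismatch: {fraction.shape} vs {delivery.shape}")
    if labels is not None and labels.shape != fraction.shape:
        raise ValueError("label map grid mismatch")
    te = acq.te_ms[echo_index]

    v = np.clip(fraction.data, 0.0, 1.0)
    n = np.maximum(1, np.round(delivery.data / acq.tr_ms))
    mz_blood = _inflow_mz_n(acq, tis, n)
    mzs_tissue = steady_state_mz(acq, tis, tis.t1_tissue_ms)

    t2_blood = np.where(
        labels.data == LABEL_VEIN, tis.t2s_vein_ms, tis.t2s_artery_ms
    ) if labels is not None else tis.t2s_artery_ms

    signal = (v * mz_blood * np.exp(-te / t2_blood)
              + (1.0 - v) * mzs_tissue * np.exp(-te / tis.t2s_tissue_ms))
    return fraction.like(signal, te_ms=te, echo_index=echo_index)


def add_rician_noise(vol: Volume, sigma: float, seed: int) -> Volume:
    """Magnitude of (signal + N(0, sigma)) + i N(0, sigma); seed-reproducible."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return vol.like(vol.data.copy())
    rng = np.random.default_rng(seed)
    re = vol.data + rng.normal(0.0, sigma, vol.shape)
    im = rng.normal(0.0, sigma, vol.shape)
    return vol.like(np.hypot(re, im), noise_sigma=sigma)


def add_bias_field(vol: Volume, amplitude: float, scale_mm: float,
                   seed: int) -> Volume:
    """Multiplicative smooth bias in [1 - a, 1 + a], low-passed at scale_mm."""
    from scipy.ndimage import gaussian_filter

    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude == 0:
        return vol.like(vol.data.copy())
    rng = np.random.default_rng(seed)
    noise = rng.normal(size=vol.shape)
    sigma_vox = scale_mm / vol.voxel_mm
    smooth = gaussian_filter(noise, sigma=sigma_vox, mode="nearest")
    smooth -= smooth.mean()
    peak = np.max(np.abs(smooth))
    field = 1.0 + (amplitude * smooth / peak if peak > 0 else 0.0)
    return vol.like(vol.data * field, bias_amplitude=amplitude)


def generate_phantom(cfg: PhantomConfig, seed: int,
                     acq: AcquisitionParams | None = None,
                     tis: TissueParams | None = None) -> dict:
    """Full phantom: trees -> ground truth maps -> per-echo noisy images.

    Returns a dict with keys ``tree``, ``fraction``, ``delivery``,
    ``labels``, ``mask`` and ``echoes`` (list of Volumes, one per TE in
    ``acq.te_ms``, with bias field and Rician noise applied per config).
    """
    acq = acq or AcquisitionParams(voxel_mm=cfg.voxel_mm)
    tis = tis or TissueParams()
    rng = np.random.default_rng(seed)
    trees = [generate_tree(cfg, int(rng.integers(2**31)), kind="artery")
             for _ in range(cfg.n_trees)]
    trees += [generate_tree(cfg, int(rng.integers(2**31)), kind="vein")
              for _ in range(cfg.n_vein_trees)]
    tree = merge_trees([t for t in trees if t.segments])
    raster = rasterize_fraction_map(tree, cfg)

    echoes = []
    for e in range(len(acq.te_ms)):
        img = simulate_tof(raster.fraction, raster.delivery, acq, tis,
                           echo_index=e, labels=raster.labels)
        if cfg.bias_amplitude > 0:
            img = add_bias_field(img, cfg.bias_amplitude, cfg.bias_scale_mm,
                                 seed=int(rng.integers(2**31)))
        if cfg.noise_sigma > 0:
            img = add_rician_noise(img, cfg.noise_sigma,
                                   seed=int(rng.integers(2**31)))
        echoes.append(img)

    return {"tree": tree, "fraction": raster.fraction,
            "delivery": raster.delivery, "labels": raster.labels,
            "mask": raster.mask, "echoes": echoes}
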