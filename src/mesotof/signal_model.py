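"""Spoiled gradient-echo steady-state and inflow signal model.

Closed-form longitudinal magnetization for static tissue and inflowing
blood under a spoiled FLASH readout, the relative flow-related
enhancement (FRE) derived from them, blood dwell time, and exhaustive
grid-search protocol optimization (Ernst angle, FRE-optimal flip angle).

Angles are degrees at every public interface and radians internally.
All magnetizations scale linearly in ``m0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionParams",
    "TissueParams",
    "FlowParams",
    "steady_state_mz",
    "inflow_blood_mz",
    "n_rf_pulses",
    "relative_fre",
    "ernst_angle_deg",
    "optimal_flip_deg",
    "blood_dwell_time_ms",
    "fre_surface",
]


@dataclass(frozen=True)
class AcquisitionParams:
    """Sequence timing and excitation parameters.

    Attributes
    ----------
    tr_ms : float
        Repetition time TR in milliseconds.
    flip_deg : float
        Excitation flip angle in degrees, in (0, 90].
    te_ms : tuple of float
        Echo times in milliseconds (one per echo); all strictly below TR.
    voxel_mm : float
        Isotropic voxel edge length in millimetres.
    phase_blip_ms : float
        Time of the phase-encoding blip relative to excitation (ms).
    """

    tr_ms: float = 20.0
    flip_deg: float = 18.0
    te_ms: tuple = (4.73,)
    voxel_mm: float = 0.3
    phase_blip_ms: float = 0.0

    def __post_init__(self):
        if self.tr_ms <= 0:
            raise ValueError(f"tr_ms must be positive, got {self.tr_ms}")
        if not (0 < self.flip_deg <= 90):
            raise ValueError(f"flip_deg must be in (0, 90], got {self.flip_deg}")
        te = tuple(float(t) for t in np.atleast_1d(self.te_ms))
        object.__setattr__(self, "te_ms", te)
        if any(t >= self.tr_ms for t in te):
            raise ValueError(f"all te_ms must be < tr_ms, got {te} vs TR {self.tr_ms}")
        if any(t < 0 for t in te):
            raise ValueError("te_ms must be non-negative")
        if self.voxel_mm <= 0:
            raise ValueError(f"voxel_mm must be positive, got {self.voxel_mm}")
        if self.phase_blip_ms < 0:
            raise ValueError("phase_blip_ms must be non-negative")

    @property
    def flip_rad(self) -> float:
        return float(np.deg2rad(self.flip_deg))


@dataclass(frozen=True)
class TissueParams:
    """Relaxation parameters of blood and static tissue.

    Defaults are longitudinal relaxation times at 7 T (blood 2100 ms,
    tissue 1950 ms); effective transverse times distinguish arteries
    (close to tissue) from veins (markedly shorter).
    """

    t1_blood_ms: float = 2100.0
    t1_tissue_ms: float = 1950.0
    m0: float = 1.0
    t2s_tissue_ms: float = 30.0
    t2s_artery_ms: float = 30.0
    t2s_vein_ms: float = 12.0

    def __post_init__(self):
        for name in ("t1_blood_ms", "t1_tissue_ms", "t2s_tissue_ms",
                     "t2s_artery_ms", "t2s_vein_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.m0 <= 0:
            raise ValueError("m0 must be positive")


@dataclass(frozen=True)
class FlowParams:
    """Blood transport parameters.

    ``delivery_ms`` is the time blood spends inside the excited volume
    before reaching the voxel of interest; it sets the number of RF
    pulses experienced. ``velocity_mm_s`` is the (plug-flow) blood speed.
    """

    delivery_ms: float = 400.0
    velocity_mm_s: float = 30.0

    def __post_init__(self):
        if self.delivery_ms < 0:
            raise ValueError(f"delivery_ms must be >= 0, got {self.delivery_ms}")
        if self.velocity_mm_s < 0:
            raise ValueError(f"velocity_mm_s must be >= 0, got {self.velocity_mm_s}")


def steady_state_mz(acq: AcquisitionParams, tis: TissueParams, t1_ms: float):
    """Steady-state longitudinal magnetization of continuously excited spins.

    Mz = M0 (1 - E) / (1 - E cos(theta)) with E = exp(-TR/T1).
    Value lies in (0, M0].
    """
    if t1_ms <= 0:
        raise ValueError(f"t1_ms must be positive, got {t1_ms}")
    e1 = np.exp(-acq.tr_ms / t1_ms)
    return tis.m0 * (1.0 - e1) / (1.0 - e1 * np.cos(acq.flip_rad))


def n_rf_pulses(delivery_ms, tr_ms):
    """Number of RF pulses experienced by blood: max(1, round(t_delivery/TR)).

    Partial TR intervals are not modelled (plug flow). Array-friendly.
    """
    n = np.maximum(1, np.round(np.asarray(delivery_ms, dtype=float) / tr_ms))
    if np.ndim(delivery_ms) == 0:
        return int(n)
    return n.astype(np.int64)


def inflow_blood_mz(acq: AcquisitionParams, tis: TissueParams, flow: FlowParams):
    """Longitudinal magnetization of inflowing blood just before the n-th pulse.

    Mz(n) = MzS_blood + (exp(-TR/T1_blood) cos(theta))^(n-1) (M0 - MzS_blood),
    with n = max(1, round(t_delivery / TR)). Fully relaxed blood (n = 1)
    returns M0 exactly; the n -> infinity limit is the blood steady state.
    """
    n = n_rf_pulses(flow.delivery_ms, acq.tr_ms)
    return _inflow_mz_n(acq, tis, n)


def _inflow_mz_n(acq: AcquisitionParams, tis: TissueParams, n_rf):
    """Inflow magnetization for explicit pulse counts (array-friendly)."""
    mzs = steady_state_mz(acq, tis, tis.t1_blood_ms)
    decay = np.exp(-acq.tr_ms / tis.t1_blood_ms) * np.cos(acq.flip_rad)
    n = np.asarray(n_rf, dtype=float)
    return mzs + decay ** (n - 1.0) * (tis.m0 - mzs)


def relative_fre(acq: AcquisitionParams, tis: TissueParams, flow: FlowParams):
    """Relative flow-related enhancement (Mz_blood - MzS_tissue)/MzS_tissue."""
    mz_blood = inflow_blood_mz(acq, tis, flow)
    mzs_tissue = steady_state_mz(acq, tis, tis.t1_tissue_ms)
    return (mz_blood - mzs_tissue) / mzs_tissue


def ernst_angle_deg(tr_ms: float, t1_ms: float) -> float:
    """Flip angle maximizing the spoiled-GRE steady state: arccos(exp(-TR/T1))."""
    if tr_ms <= 0 or t1_ms <= 0:
        raise ValueError("tr_ms and t1_ms must be positive")
    return float(np.rad2deg(np.arccos(np.exp(-tr_ms / t1_ms))))


def optimal_flip_deg(
    acq: AcquisitionParams,
    tis: TissueParams,
    delivery_ms: float,
    grid_step_deg: float = 0.05,
    round_deg: bool = True,
):
    """Flip angle in (0, 90] maximizing relative FRE at fixed TR and delivery.

    Exhaustive grid search with step ``grid_step_deg``; ties break toward
    the smaller angle. Rounded to the nearest integer degree by default
    (reporting convention).
    """
    if grid_step_deg <= 0:
        raise ValueError("grid_step_deg must be positive")
    flips = np.arange(grid_step_deg, 90.0 + grid_step_deg / 2, grid_step_deg)
    if flips.size == 0:
        raise ValueError("empty flip-angle grid")
    mzs_tissue = _steady_state_grid(acq.tr_ms, flips, tis.t1_tissue_ms, tis.m0)
    mzs_blood = _steady_state_grid(acq.tr_ms, flips, tis.t1_blood_ms, tis.m0)
    n = n_rf_pulses(delivery_ms, acq.tr_ms)
    decay = np.exp(-acq.tr_ms / tis.t1_blood_ms) * np.cos(np.deg2rad(flips))
    mz_blood = mzs_blood + decay ** (n - 1) * (tis.m0 - mzs_blood)
    fre = (mz_blood - mzs_tissue) / mzs_tissue
    best = flips[int(np.argmax(fre))]  # argmax returns first max: smaller angle
    return float(np.round(best)) if round_deg else float(best)


def _steady_state_grid(tr_ms, flip_deg, t1_ms, m0):
    e1 = np.exp(-tr_ms / t1_ms)
    return m0 * (1.0 - e1) / (1.0 - e1 * np.cos(np.deg2rad(flip_deg)))


def blood_dwell_time_ms(voxel_mm, velocity_mm_s):
    """Average voxel transit time of blood: 1000 * voxel / velocity (ms).

    Zero velocity returns infinity (stationary spins never leave the voxel);
    negative velocity is rejected.
    """
    v = np.asarray(velocity_mm_s, dtype=float)
    if np.any(v < 0):
        raise ValueError("velocity_mm_s must be >= 0")
    l = np.asarray(voxel_mm, dtype=float)
    if np.any(l <= 0):
        raise ValueError("voxel_mm must be positive")
    with np.errstate(divide="ignore"):
        out = 1000.0 * l / v
    if np.ndim(out) == 0:
        return float(out)
    return out


def fre_surface(
    acq: AcquisitionParams,
    tis: TissueParams,
    delivery_grid,
    flip_grid=None,
    tr_grid=None,
) -> pd.DataFrame:
    """Dense table of relative FRE over delivery x flip (or delivery x TR).

    Exactly one of ``flip_grid`` / ``tr_grid`` may be given; when neither
    is, the acquisition's own flip angle is used. Returns a DataFrame with
    columns ``tr_ms, flip_deg, delivery_ms, fre`` (CSV-writable).
    """
    deliveries = np.atleast_1d(np.asarray(delivery_grid, dtype=float))
    if deliveries.size == 0:
        raise ValueError("empty delivery grid")
    if flip_grid is not None and tr_grid is not None:
        raise ValueError("give at most one of flip_grid / tr_grid")
    rows = []
    if tr_grid is not None:
        trs = np.atleast_1d(np.asarray(tr_grid, dtype=float))
        if trs.size == 0:
            raise ValueError("empty TR grid")
        for tr in trs:
            a = AcquisitionParams(tr_ms=tr, flip_deg=acq.flip_deg,
                                  te_ms=(min(acq.te_ms[0], tr * 0.5),),
                                  voxel_mm=acq.voxel_mm)
            for d in deliveries:
                rows.append((tr, acq.flip_deg, d,
                             float(relative_fre(a, tis, FlowParams(delivery_ms=d)))))
    else:
        flips = (np.atleast_1d(np.asarray(flip_grid, dtype=float))
                 if flip_grid is not None else np.array([acq.flip_deg]))
        if flips.size == 0:
            raise ValueError("empty flip grid")
        for f in flips:
            a = AcquisitionParams(tr_ms=acq.tr_ms, flip_deg=f, te_ms=acq.te_ms,
                                  voxel_mm=acq.voxel_mm)
            for d in deliveries:
                rows.append((acq.tr_ms, f, d,
                             float(relative_fre(a, tis, FlowParams(delivery_ms=d)))))
    return pd.DataFrame(rows, columns=["tr_ms", "flip_deg", "delivery_ms", "fre"])
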