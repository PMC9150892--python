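import numpy as np
import pytest

from mesotof.phantom import (
    PhantomConfig,
    VesselSegment,
    VesselTree,
    generate_phantom,
    rasterize_fraction_map,
    simulate_tof,
)
from mesotof.signal_model import AcquisitionParams, FlowParams, TissueParams


@pytest.fixture(scope="session")
def acq():
    return AcquisitionParams(tr_ms=20.0, flip_deg=18.0, te_ms=(7.05, 14.0),
                             voxel_mm=0.3)


@pytest.fixture(scope="session")
def tis():
    return TissueParams()


@pytest.fixture(scope="session")
def default_phantom(acq, tis):
    """Noiseless default-config phantom (64^3); noise is added per test."""
    cfg = PhantomConfig()
    out = generate_phantom(cfg, seed=42, acq=acq, tis=tis)
    out["cfg"] = cfg
    return out


from functools import lru_cache


@lru_cache(maxsize=32)
def straight_cylinder_phantom(diameter_mm, voxel_mm, fov_mm=6.0,
                              delivery_ms=300.0, kind="artery",
                              acq=None, tis=None):
    """Single centred axis-aligned cylinder along x, through voxel centres."""
    acq = acq or AcquisitionParams(te_ms=(7.05, 14.0), voxel_mm=voxel_mm)
    tis = tis or TissueParams()
    cfg = PhantomConfig(fov_mm=(fov_mm,) * 3, voxel_mm=voxel_mm)
    n = cfg.grid_shape[1]
    c = (n // 2 + 0.5) * voxel_mm  # a voxel-centre coordinate
    seg = VesselSegment([voxel_mm / 2, c, c], [fov_mm - voxel_mm / 2, c, c],
                        diameter_mm, 30.0, delivery_ms, kind=kind)
    tree = VesselTree([seg])
    raster = rasterize_fraction_map(tree, cfg)
    echoes = [simulate_tof(raster.fraction, raster.delivery, acq, tis,
                           echo_index=e, labels=raster.labels)
              for e in range(len(acq.te_ms))]
    return {"cfg": cfg, "tree": tree, "raster": raster, "echoes": echoes,
            "acq": acq, "tis": tis}


@pytest.fixture(scope="session")
def labelled_vessel_phantom():
    """Deterministic phantom with 5 artery + 5 vein parallel cylinders.

    All vessels are bright (short delivery, mimicking through-flowing
    sinuses for the veins) so that artery/vein separation must come from
    the two-echo T2* contrast alone.
    """
    voxel = 0.3
    fov = 12.0
    acq = AcquisitionParams(te_ms=(7.05, 14.0), voxel_mm=voxel)
    tis = TissueParams()  # artery T2* 30 ms, vein 12 ms
    cfg = PhantomConfig(fov_mm=(fov,) * 3, voxel_mm=voxel)
    n = cfg.grid_shape[1]
    segs = []
    ys = np.linspace(1.5, fov - 1.5, 5)
    for i, y in enumerate(ys):
        yc = (round(y / voxel - 0.5) + 0.5) * voxel
        z_a = (round(0.3 * n) + 0.5) * voxel
        z_v = (round(0.7 * n) + 0.5) * voxel
        segs.append(VesselSegment([voxel / 2, yc, z_a],
                                  [fov - voxel / 2, yc, z_a],
                                  1.2, 50.0, 250.0, kind="artery"))
        segs.append(VesselSegment([voxel / 2, yc, z_v],
                                  [fov - voxel / 2, yc, z_v],
                                  1.2, 50.0, 250.0, kind="vein"))
    tree = VesselTree(segs)
    raster = rasterize_fraction_map(tree, cfg)
    echoes = [simulate_tof(raster.fraction, raster.delivery, acq, tis,
                           echo_index=e, labels=raster.labels)
              for e in range(2)]
    return {"cfg": cfg, "tree": tree, "raster": raster, "echoes": echoes,
            "acq": acq, "tis": tis}
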