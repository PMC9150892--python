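"""Shared volume container and NIfTI-1 / CSV / PNG I/O.

Conventions used everywhere in the package: world coordinates in mm, RAS
orientation, 0-based voxel indices, voxel centres at (i + 0.5) * l.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume", "read_volume", "write_volume", "write_provenance"]


@dataclass
class Volume:
    """A 3D scalar grid with voxel size, world affine and free-form metadata."""

    data: np.ndarray
    voxel_mm: np.ndarray
    affine: np.ndarray = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3D, got shape {self.data.shape}")
        self.voxel_mm = np.broadcast_to(
            np.asarray(self.voxel_mm, dtype=float), (3,)).copy()
        if np.any(self.voxel_mm <= 0):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_mm}")
        if self.affine is None:
            # RAS, voxel centres at (i + 0.5) * l
            self.affine = np.diag([*self.voxel_mm, 1.0])
            self.affine[:3, 3] = self.voxel_mm / 2.0
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def shape(self):
        return self.data.shape

    @property
    def is_isotropic(self) -> bool:
        return bool(np.allclose(self.voxel_mm, self.voxel_mm[0], rtol=1e-6))

    def require_isotropic(self, context: str = "operation"):
        if not self.is_isotropic:
            raise ValueError(
                f"{context} requires isotropic voxels, got {self.voxel_mm}")

    def like(self, data: np.ndarray, **meta) -> "Volume":
        """New Volume on the same grid (shape-checked)."""
        data = np.asarray(data)
        if data.shape != self.data.shape:
            raise ValueError(
                f"grid mismatch: {data.shape} vs {self.data.shape}")
        return Volume(data, self.voxel_mm.copy(), self.affine.copy(),
                      {**self.meta, **meta})


def read_volume(path) -> Volume:
    """Read a NIfTI-1 volume (data + voxel size + affine, float64)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # malformed header
        raise ValueError(f"cannot read NIfTI volume {path}: {exc}") from exc
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return Volume(data, zooms, np.asarray(img.affine, dtype=float),
                  {"source": str(path)})


def write_volume(vol: Volume, path) -> Path:
    """Write a Volume as NIfTI-1 (lossless float64 round-trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), vol.affine)
    img.header.set_zooms(tuple(vol.voxel_mm))
    nib.save(img, str(path))
    return path


def write_provenance(path, config: dict, seed=None) -> Path:
    """JSON sidecar recording config, seed and package versions."""
    import mesotof

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "config": _jsonable(config),
        "seed": seed,
        "versions": {
            "mesotof": mesotof.__version__,
            "numpy": np.__version__,
            "nibabel": nib.__version__,
        },
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        from dataclasses import asdict

        return _jsonable(asdict(obj))
    return obj
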