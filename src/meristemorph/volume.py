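"""Confocal-like image stacks: the 3D scalar volumes the pipeline consumes.

Axis order is (z, y, x), coordinates 0-based; the physical position of voxel
(iz, iy, ix) is (iz*dz, iy*dy, ix*dx) in µm.  The default z step is 0.4 µm,
the acquisition step of the stacks this pipeline emulates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import tifffile

__all__ = ["VolumeStack"]


@dataclass
class VolumeStack:
    """3D intensity volume with voxel spacing in µm, axis order (z, y, x)."""

    intensities: np.ndarray
    voxel_size: tuple[float, float, float] = (0.4, 0.5, 0.5)

    def __post_init__(self) -> None:
        a = np.asarray(self.intensities)
        if a.ndim != 3:
            raise ValueError("intensities must be a 3D (z, y, x) array")
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        self.intensities = a
        self.voxel_size = tuple(float(s) for s in self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def save_tiff(self, path) -> None:
        """Multi-page TIFF, one page per z slice, voxel sizes in metadata."""
        dz, dy, dx = self.voxel_size
        tifffile.imwrite(
            path,
            np.asarray(self.intensities, dtype=np.float32),
            resolution=(1.0 / dx, 1.0 / dy),
            metadata={"spacing": dz, "unit": "um",
                      "voxel_size_zyx_um": [dz, dy, dx]},
        )

    @classmethod
    def load_tiff(cls, path) -> "VolumeStack":
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            voxel = None
            desc = tf.pages[0].description or ""
            try:
                meta = json.loads(desc)
            except (json.JSONDecodeError, TypeError):
                meta = {}
            if isinstance(meta, dict) and "voxel_size_zyx_um" in meta:
                voxel = tuple(meta["voxel_size_zyx_um"])
            if voxel is None:
                # ImageJ-style: spacing in description, resolution tags for xy
                spacing = meta.get("spacing", 0.4) if isinstance(meta, dict) else 0.4
                page = tf.pages[0]
                try:
                    xr = page.tags["XResolution"].value
                    yr = page.tags["YResolution"].value
                    dx = xr[1] / xr[0]
                    dy = yr[1] / yr[0]
                except (KeyError, ZeroDivisionError):
                    dx = dy = 0.5
                voxel = (float(spacing), float(dy), float(dx))
        if data.ndim == 2:
            data = data[None]
        return cls(data, voxel)
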