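"""In-memory container for one channel/timepoint of a 3D fluorescence stack.

Axis convention throughout the package: arrays are indexed (z, y, x),
0-based, and ``voxel_size`` is the matching (dz, dy, dx) triple in µm.
Physical positions refer to voxel centers, so voxel index ``i`` along an
axis sits at ``i * d`` µm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class ImageVolume:
    """One channel at one timepoint of a volumetric acquisition.

    Parameters
    ----------
    voxels
        3D array of non-negative intensities, indexed (z, y, x).
    voxel_size
        Physical voxel spacing (dz, dy, dx) in µm.
    channel
        One of ``"green"``, ``"red"`` or ``"filler"``.
    timepoint
        Acquisition index (0 = baseline, before photoconversion).
    wavelength_nm
        Optional excitation wavelength tag (e.g. 980 or 1040 for
        two-photon green/red acquisition).
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    channel: str = "green"
    timepoint: int = 0
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got shape {self.voxels.shape}")
        if min(self.voxels.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive values, got {self.voxel_size}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("intensities must be finite")
        if self.channel not in ("green", "red", "filler"):
            raise ValueError(f"unknown channel {self.channel!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def physical_extent(self) -> tuple[float, float, float]:
        """Physical size of the grid (µm), counting voxel centers 0..n-1."""
        return tuple(s * d for s, d in zip(self.shape, self.voxel_size))

    def with_voxels(self, voxels: np.ndarray) -> "ImageVolume":
        """Copy of this volume with the voxel data replaced, metadata kept."""
        return replace(self, voxels=voxels)

    # ------------------------------------------------------------------ I/O

    def to_tiff(self, path: str | Path) -> None:
        """Write as OME-TIFF with voxel-size metadata (µm)."""
        dz, dy, dx = self.voxel_size
        tifffile.imwrite(
            str(path),
            np.asarray(self.voxels, dtype=np.float32),
            ome=True,
            metadata={
                "axes": "ZYX",
                "PhysicalSizeZ": dz,
                "PhysicalSizeY": dy,
                "PhysicalSizeX": dx,
                "PhysicalSizeZUnit": "µm",
                "PhysicalSizeYUnit": "µm",
                "PhysicalSizeXUnit": "µm",
            },
        )

    @classmethod
    def from_tiff(
        cls,
        path: str | Path,
        channel: str = "green",
        timepoint: int = 0,
        voxel_size: tuple[float, float, float] | None = None,
    ) -> "ImageVolume":
        """Read a (OME-)TIFF stack; voxel size from OME metadata unless given."""
        with tifffile.TiffFile(str(path)) as tif:
            data = tif.asarray()
            if voxel_size is None:
                voxel_size = _voxel_size_from_ome(tif)
        if voxel_size is None:
            raise ValueError(
                f"{path}: no voxel-size metadata found; pass voxel_size explicitly"
            )
        if data.ndim == 2:
            data = data[None]
        return cls(voxels=np.asarray(data, dtype=np.float32), voxel_size=voxel_size,
                   channel=channel, timepoint=timepoint)


def _voxel_size_from_ome(tif: "tifffile.TiffFile") -> tuple[float, float, float] | None:
    if not tif.is_ome:
        return None
    try:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tif.ome_metadata)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        px = root.find(".//ome:Pixels", ns)
        if px is None:
            return None
        return (
            float(px.get("PhysicalSizeZ", "nan")),
            float(px.get("PhysicalSizeY", "nan")),
            float(px.get("PhysicalSizeX", "nan")),
        )
    except Exception:
        return None
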