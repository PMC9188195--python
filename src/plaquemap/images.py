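"""Physical-unit image containers.

All sizes are in micrometres. Arrays are plain numpy arrays; the containers
only add the metadata the pipelines need (pixel/voxel size, optional ROI).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Plane2D:
    """A single-channel 2D intensity image with a physical pixel size.

    Parameters
    ----------
    data
        2D array of intensities (or booleans for masks).
    pixel_size
        Edge length of a pixel in micrometres. Must be positive.
    roi
        Optional boolean mask of the same shape marking the analyzed tissue
        region.
    """

    data: np.ndarray
    pixel_size: float
    roi: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"Plane2D requires a 2D array, got ndim={self.data.ndim}")
        if not (self.pixel_size > 0):
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        if self.roi is not None:
            self.roi = np.asarray(self.roi, dtype=bool)
            if self.roi.shape != self.data.shape:
                raise ValueError("roi shape must match data shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def pixel_area_mm2(self) -> float:
        """Area of one pixel in mm^2."""
        return (self.pixel_size * 1e-3) ** 2


@dataclass
class Volume3D:
    """A 3D intensity or binary volume with per-axis voxel size.

    ``voxel_size`` is ordered (z, y, x) to match the array axes.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel: str | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D requires a 3D array, got ndim={self.data.ndim}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def is_isotropic(self) -> bool:
        z, y, x = self.voxel_size
        return np.isclose(z, y) and np.isclose(y, x)

    def voxel_volume_um3(self) -> float:
        z, y, x = self.voxel_size
        return z * y * x
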