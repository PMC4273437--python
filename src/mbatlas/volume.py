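"""The universal 3D image carrier.

A :class:`Volume` is a scalar grid in ``(z, y, x)`` index order with physical
voxel spacing in µm.  All geometric quantities downstream (transforms,
centroids, distances) are expressed in physical µm; voxel grids are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Volume"]


@dataclass
class Volume:
    data: np.ndarray                       # 3D, (z, y, x)
    spacing: tuple[float, float, float]    # µm per voxel, (z, y, x)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # µm offset
    channel_tag: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def is_isotropic(self) -> bool:
        return np.allclose(self.spacing, self.spacing[0], rtol=1e-6)

    def physical_extent(self) -> tuple[float, float, float]:
        """Edge lengths of the grid in µm."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def with_data(self, data: np.ndarray, channel_tag: str | None = None) -> "Volume":
        """A new volume on the same grid with different voxel values."""
        return replace(
            self,
            data=np.asarray(data),
            channel_tag=self.channel_tag if channel_tag is None else channel_tag,
        )

    def voxel_volume(self) -> float:
        """Volume of a single voxel in µm³."""
        return float(np.prod(self.spacing))

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map (…, 3) voxel indices to physical (z, y, x) µm coordinates."""
        return np.asarray(idx, float) * np.array(self.spacing) + np.array(self.origin)

    def physical_to_index(self, pos: np.ndarray) -> np.ndarray:
        return (np.asarray(pos, float) - np.array(self.origin)) / np.array(self.spacing)
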