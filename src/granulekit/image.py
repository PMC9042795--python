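"""Physical-unit-aware image container.

All granulekit operations consume and produce :class:`ImageStack`, a named
multi-channel voxel grid that carries its voxel size in nanometres. Axis
order is ``(z, y, x)`` for 3D data and ``(y, x)`` for 2D; voxel indices are
0-based and physical coordinates are measured in nm from the corner of voxel
``(0, 0, 0)`` (so the centre of voxel ``i`` sits at ``(i + 0.5) * voxel``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageStack", "NM_PER_UM", "UM3_PER_LITER"]

NM_PER_UM = 1e3
#: 1 L = 1 dm^3 = 1e15 µm^3
UM3_PER_LITER = 1e15


@dataclass
class ImageStack:
    """Multi-channel voxel grid with physical voxel size.

    Parameters
    ----------
    data:
        Array of shape ``(n_channels, *spatial)``; spatial is ``(z, y, x)``
        or ``(y, x)``.
    channels:
        Channel names, one per leading-axis entry.
    voxel_size_nm:
        Physical edge length of a voxel along each spatial axis, in nm.
    """

    data: np.ndarray
    channels: list[str] = field(default_factory=lambda: ["ch0"])
    voxel_size_nm: tuple[float, ...] = (100.0, 100.0, 100.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim < 3:
            # allow a bare 2D/3D single-channel array for convenience
            self.data = self.data[np.newaxis]
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel names for "
                f"{self.data.shape[0]} channel planes"
            )
        self.voxel_size_nm = tuple(float(v) for v in self.voxel_size_nm)
        if len(self.voxel_size_nm) != self.data.ndim - 1:
            raise ValueError(
                f"voxel_size_nm has {len(self.voxel_size_nm)} entries for "
                f"{self.data.ndim - 1} spatial axes"
            )
        if any(v <= 0 for v in self.voxel_size_nm):
            raise ValueError("voxel size must be strictly positive on every axis")

    # -- accessors ---------------------------------------------------------
    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.data.shape[1:]

    @property
    def ndim_spatial(self) -> int:
        return self.data.ndim - 1

    @property
    def voxel_volume_um3(self) -> float:
        """Volume (3D) or area (2D) of one voxel in µm^3 (µm^2)."""
        return float(np.prod(np.asarray(self.voxel_size_nm) / NM_PER_UM))

    def channel(self, name: str | int | None = None) -> np.ndarray:
        """Return one channel plane; default is the first channel."""
        if name is None:
            return self.data[0]
        if isinstance(name, (int, np.integer)):
            return self.data[int(name)]
        try:
            return self.data[self.channels.index(name)]
        except ValueError:
            raise KeyError(
                f"no channel {name!r}; have {self.channels}"
            ) from None

    def voxel_centers_nm(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centres along one spatial axis."""
        n = self.spatial_shape[axis]
        return (np.arange(n) + 0.5) * self.voxel_size_nm[axis]
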