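"""Core containers shared across the pipeline.

Conventions
-----------
* Arrays are indexed ``(z, y, x)``; every position or size triple in this
  package follows the same ``(z, y, x)`` order.  CSV writers emit
  ``x_um, y_um, z_um`` columns for human consumption (see :mod:`somapeaks.io`).
* A voxel with index ``i`` occupies ``[i * h, (i + 1) * h)`` micrometres along
  its axis (voxel edge ``h``); its *position* is the voxel centre
  ``(i + 0.5) * h``.  All distances are Euclidean in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeStack", "RegionPointSet", "SomaDetection"]


@dataclass
class VolumeStack:
    """A 3D grayscale intensity grid with physical voxel size.

    Parameters
    ----------
    data
        Non-negative intensity array, indexed ``(z, y, x)``.
    voxel_size
        Voxel edge lengths in micrometres, ``(z, y, x)``.
    origin
        Voxel-index offset of ``data[0, 0, 0]`` within a parent stack;
        ``(0, 0, 0)`` for a stand-alone stack.  Used by block splitting.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive lengths, got {self.voxel_size}")
        self.origin = tuple(int(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical size of the stack along each axis (z, y, x), in um."""
        return tuple(n * v for n, v in zip(self.data.shape, self.voxel_size))

    def positions_um(self, indices: np.ndarray) -> np.ndarray:
        """Voxel-centre positions (um) for an ``(n, 3)`` array of indices."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return (idx + 0.5) * np.asarray(self.voxel_size)


@dataclass
class RegionPointSet:
    """One 26-connected foreground region: the unit density-peak clustering works on.

    ``indices`` are voxel indices into the parent stack, ``positions_um`` the
    corresponding voxel-centre positions, ``intensities`` the original (not
    binarized) gray values.
    """

    indices: np.ndarray  # (n, 3) int, (z, y, x)
    positions_um: np.ndarray  # (n, 3) float
    intensities: np.ndarray  # (n,) float
    region_id: int

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.indices) == 0:
            raise ValueError("a RegionPointSet must contain at least one voxel")
        if not (len(self.indices) == len(self.positions_um) == len(self.intensities)):
            raise ValueError("indices, positions and intensities must have equal length")

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def linear_indices(self) -> np.ndarray:
        """Lexicographic rank of each voxel index; used for deterministic tie-breaks."""
        order = np.lexsort(self.indices.T[::-1])
        rank = np.empty(len(order), dtype=np.int64)
        rank[order] = np.arange(len(order))
        return rank


@dataclass
class SomaDetection:
    """A located soma: its centre, the region it came from, and its cluster voxels."""

    center_um: np.ndarray  # (3,) (z, y, x)
    region_id: int
    label: int
    member_indices: np.ndarray = field(default=None)  # (n, 3) voxel indices
    member_positions_um: np.ndarray = field(default=None)
    member_intensities: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.center_um = np.asarray(self.center_um, dtype=float)

    @property
    def n_voxels(self) -> int:
        return 0 if self.member_indices is None else len(self.member_indices)
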