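"""Per-soma morphometrics: radius, overlap-measure, mean gray value.

These are the summary statistics used to characterise a segmented population:

* *radius* — mean Euclidean distance from a soma's centre to its perimeter
  voxels (members with at least one 6-connected face neighbour outside the
  cluster);
* *overlap-measure* — for a soma and its closest detected neighbour, the sum
  of the two radii divided by the centre distance; a value above 1 marks a
  touching pair;
* *mean gray* — the average original intensity over the soma's voxels.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .types import SomaDetection, VolumeStack

__all__ = ["soma_radius", "overlap_measure", "mean_gray", "morphometry_table"]

_FACE_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def soma_radius(detection: SomaDetection) -> float:
    """Average distance (um) from the detection's centre to its perimeter voxels.

    A member voxel is on the perimeter when at least one of its 6 face
    neighbours is not a member (voxels beyond the stack boundary count as
    outside).  A single-voxel cluster has radius 0 (with a warning).
    """
    idx = detection.member_indices
    if idx is None or len(idx) == 0:
        raise ValueError("detection carries no member voxels")
    if len(idx) == 1:
        warnings.warn("single-voxel cluster: radius is 0", stacklevel=2)
        return 0.0
    members = set(map(tuple, idx))
    on_perimeter = np.array(
        [any(tuple(v + o) not in members for o in _FACE_OFFSETS) for v in idx]
    )
    per_pos = detection.member_positions_um[on_perimeter]
    return float(np.linalg.norm(per_pos - detection.center_um, axis=1).mean())


def overlap_measure(
    detections: list[SomaDetection], radii: np.ndarray | None = None
) -> np.ndarray:
    """Overlap-measure per soma: (own radius + closest soma's radius) / distance.

    The partner of each soma is its closest other detection (the relation need
    not be symmetric).  Requires at least two detections.
    """
    if len(detections) < 2:
        raise ValueError("overlap_measure needs at least two detections")
    if radii is None:
        radii = np.array([soma_radius(d) for d in detections])
    radii = np.asarray(radii, dtype=float)
    centers = np.array([d.center_um for d in detections])
    D = cdist(centers, centers)
    np.fill_diagonal(D, np.inf)
    partner = D.argmin(axis=1)
    dist = D[np.arange(len(detections)), partner]
    return (radii + radii[partner]) / dist


def mean_gray(detection: SomaDetection, stack: VolumeStack | None = None) -> float:
    """Arithmetic mean of the original intensities over the soma's voxels."""
    if stack is not None:
        vals = stack.data[tuple(detection.member_indices.T)]
    else:
        vals = detection.member_intensities
        if vals is None:
            raise ValueError("no intensities stored and no stack given")
    return float(np.mean(vals))


def morphometry_table(
    detections: list[SomaDetection], stack: VolumeStack | None = None
) -> pd.DataFrame:
    """Radius / overlap-measure / mean-gray table, one row per detection.

    ``overlap_measure`` is NaN when fewer than two somas were detected.
    """
    radii = np.array([soma_radius(d) for d in detections]) if detections else np.empty(0)
    if len(detections) >= 2:
        overlap = overlap_measure(detections, radii)
    else:
        overlap = np.full(len(detections), np.nan)
    return pd.DataFrame(
        {
            "label": [d.label for d in detections],
            "radius_um": radii,
            "overlap_measure": overlap,
            "mean_gray": [mean_gray(d, stack) for d in detections],
            "n_voxels": [d.n_voxels for d in detections],
        }
    )
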