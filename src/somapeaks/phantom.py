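"""Synthetic soma phantoms with Poisson counting noise and known ground truth.

The generator emulates the standard simulation design for touching-soma
detection benchmarks: each stack holds spherical somas of fixed radius on a
flat background, every voxel an independent Poisson draw whose mean is
``I_o + I_b`` inside a soma and ``I_b`` outside.  Contrast is parameterised by
the signal-to-noise ratio

    SNR = I_o / sqrt(I_o + I_b),

i.e. the signal amplitude over the Poisson noise standard deviation inside a
soma.  The canonical study conditions are a background mean ``I_b = 100``,
soma radius 10 um, and a single pair of somas per stack at centre distance
``d`` between 2 and 26 um, for SNR in {1, 2, 4, 6}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .types import VolumeStack

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "snr_to_intensity",
    "generate_stack",
    "generate_pair_series",
    "pair_spec",
]

#: Default stack geometry for pair phantoms: 100^3 voxels of 2 x 2 x 2 um^3,
#: matching the voxel size of the merged experimental stacks the method
#: targets.  The pair sits at the stack centre, displaced along x.
DEFAULT_SHAPE = (100, 100, 100)
DEFAULT_VOXEL = (2.0, 2.0, 2.0)
DEFAULT_SNR_GRID = (1.0, 2.0, 4.0, 6.0)
DEFAULT_D_GRID = (2.0, 6.0, 10.0, 14.0, 18.0, 22.0, 26.0)


def snr_to_intensity(snr: float, I_b: float) -> float:
    """Signal mean ``I_o`` that realises a requested SNR over background ``I_b``.

    Inverts ``snr = I_o / sqrt(I_o + I_b)``, i.e. returns the positive root of
    ``I_o**2 - snr**2 * I_o - snr**2 * I_b = 0``.

    >>> round(snr_to_intensity(1.0, 100.0), 4)
    10.5125
    """
    if snr < 0 or I_b < 0:
        raise ValueError(f"snr and I_b must be non-negative, got snr={snr}, I_b={I_b}")
    return 0.5 * (snr**2 + snr * math.sqrt(snr**2 + 4.0 * I_b))


@dataclass
class GroundTruth:
    """True soma centres and radii for a generated phantom (um, (z, y, x))."""

    centers_um: np.ndarray  # (k, 3)
    radii_um: np.ndarray  # (k,)

    def __post_init__(self) -> None:
        self.centers_um = np.asarray(self.centers_um, dtype=float).reshape(-1, 3)
        self.radii_um = np.asarray(self.radii_um, dtype=float).reshape(-1)
        if len(self.centers_um) != len(self.radii_um):
            raise ValueError("centers and radii must have equal length")

    def __len__(self) -> int:
        return len(self.centers_um)


@dataclass
class PhantomSpec:
    """Recipe for one synthetic stack.

    ``somas`` is a sequence of ``(center_um, radius_um)`` with centres in
    ``(z, y, x)`` micrometres.  Every soma sphere must lie fully inside the
    stack; a voxel belongs to a soma when its centre is within ``radius_um``
    of the soma centre (hard sphere, no partial-volume blending).
    """

    stack_shape: tuple[int, int, int] = DEFAULT_SHAPE
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL
    somas: Sequence[tuple[Sequence[float], float]] = field(default_factory=list)
    I_b: float = 100.0
    snr: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.stack_shape):
            raise ValueError("stack_shape must be at least 1 voxel per axis")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        if self.I_b < 0:
            raise ValueError("background mean I_b must be non-negative")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        extent = [n * v for n, v in zip(self.stack_shape, self.voxel_size)]
        for center, radius in self.somas:
            if radius <= 0:
                raise ValueError("soma radius must be positive")
            for c, lim in zip(center, extent):
                if c - radius < 0 or c + radius > lim:
                    raise ValueError(
                        f"soma at {tuple(center)} (radius {radius} um) extends outside "
                        f"the stack extent {tuple(extent)} um"
                    )


def _soma_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean mask of voxels whose centres fall inside any soma sphere."""
    mask = np.zeros(spec.stack_shape, dtype=bool)
    vox = np.asarray(spec.voxel_size)
    for center, radius in spec.somas:
        center = np.asarray(center, dtype=float)
        # restrict to the sphere's bounding box for speed
        lo = np.maximum(np.floor((center - radius) / vox - 0.5).astype(int), 0)
        hi = np.minimum(np.ceil((center + radius) / vox + 0.5).astype(int) + 1, spec.stack_shape)
        grids = np.meshgrid(
            *[(np.arange(l, h) + 0.5) * v for l, h, v in zip(lo, hi, vox)], indexing="ij"
        )
        dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        sub = tuple(slice(l, h) for l, h in zip(lo, hi))
        mask[sub] |= dist2 <= radius**2
    return mask


def generate_stack(spec: PhantomSpec) -> tuple[VolumeStack, GroundTruth]:
    """Draw one phantom stack and its ground truth.

    Every voxel is an independent Poisson draw with mean ``I_o + I_b`` inside
    a soma sphere and ``I_b`` outside, where ``I_o`` realises ``spec.snr``.
    Counts are stored as 16-bit integers.  Fixed ``spec.seed`` gives a
    bit-identical stack.
    """
    I_o = snr_to_intensity(spec.snr, spec.I_b)
    mean = np.full(spec.stack_shape, spec.I_b, dtype=float)
    if spec.somas:
        mean[_soma_mask(spec)] += I_o
    rng = np.random.default_rng(spec.seed)
    data = rng.poisson(mean).astype(np.uint16)
    stack = VolumeStack(data=data, voxel_size=spec.voxel_size)
    if spec.somas:
        centers = np.asarray([c for c, _ in spec.somas], dtype=float)
        radii = np.asarray([r for _, r in spec.somas], dtype=float)
    else:
        centers = np.empty((0, 3))
        radii = np.empty((0,))
    return stack, GroundTruth(centers_um=centers, radii_um=radii)


def pair_spec(
    snr: float,
    d: float,
    radius: float = 10.0,
    I_b: float = 100.0,
    stack_shape: tuple[int, int, int] = DEFAULT_SHAPE,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL,
    seed: int = 0,
) -> PhantomSpec:
    """Spec for a single touching-pair phantom: two somas ``d`` um apart.

    The pair is centred in the stack and displaced along the x axis.
    """
    extent = np.asarray([n * v for n, v in zip(stack_shape, voxel_size)])
    c = extent / 2.0
    a = c.copy()
    b = c.copy()
    a[2] -= d / 2.0
    b[2] += d / 2.0
    return PhantomSpec(
        stack_shape=stack_shape,
        voxel_size=voxel_size,
        somas=[(tuple(a), radius), (tuple(b), radius)],
        I_b=I_b,
        snr=snr,
        seed=seed,
    )


def generate_pair_series(
    snr_list: Sequence[float] = DEFAULT_SNR_GRID,
    d_list: Sequence[float] = DEFAULT_D_GRID,
    radius: float = 10.0,
    seed: int = 0,
    I_b: float = 100.0,
    stack_shape: tuple[int, int, int] = DEFAULT_SHAPE,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL,
) -> list[tuple[float, float, VolumeStack, GroundTruth]]:
    """Generate the full (SNR, d) grid of pair phantoms.

    Returns one ``(snr, d, stack, truth)`` entry per combination, in
    row-major (snr-outer) order; the defaults give the canonical 28-stack
    simulation set.  Each stack uses its own RNG stream derived from
    ``(seed, stack_index)`` so the series is reproducible element-wise.
    """
    if not len(snr_list) or not len(d_list):
        raise ValueError("snr_list and d_list must be non-empty")
    out = []
    k = 0
    for snr in snr_list:
        for d in d_list:
            spec = pair_spec(
                snr, d, radius=radius, I_b=I_b, stack_shape=stack_shape,
                voxel_size=voxel_size, seed=[int(seed), k],
            )
            stack, truth = generate_stack(spec)
            out.append((float(snr), float(d), stack, truth))
            k += 1
    return out
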