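"""Soma localization and segmentation by modified density-peak clustering.

Density-peak clustering characterises each point by two quantities: the local
density ``rho`` and the minimum distance ``delta`` to any point of higher
density.  Cluster centres — soma positions — combine high ``rho`` with large
``delta``, so they stand isolated in the (rho, delta) feature plane.  The
original formulation picks centres by hand from a decision graph; here centre
selection is automatic:

1. ``rho_i`` is an intensity-weighted Gaussian-kernel sum over region points
   within a window ``R = 2 * sigma`` of ``p_i``, normalised so the region
   maximum is 1.
2. ``delta_i`` is the distance to the nearest strictly-higher-density point,
   divided by the region diameter; the region's density maximum gets 1.
3. The (rho, delta) points are histogrammed on a 0.001-wide grid and smoothed
   with an 11 x 11 Gaussian window (width 3 grid units); the smoothed density
   at a point's bin is its *feature density* ``Lambda``, expressed as a
   fraction of the region's points.
4. Candidate centres are isolated feature points: ``Lambda <= thre_selective``
   and ``delta * diameter >= R_min`` (the minimum soma radius).  Redundant
   candidates closer than ``R_min`` to a stronger one are pruned, remaining
   points are assigned to the cluster of their nearest higher-density
   neighbour.

All operations work per 26-connected foreground region, which both matches
the model (a region holds one or a few touching somas) and keeps the
minimum-distance search local.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .types import RegionPointSet, SomaDetection, VolumeStack

__all__ = [
    "DensityConfig",
    "CenterSelectConfig",
    "RegionFeatures",
    "compute_rho",
    "density_field",
    "compute_rho_image",
    "compute_delta",
    "region_diameter",
    "build_feature_image",
    "feature_density",
    "select_candidates",
    "prune_candidates",
    "assign_clusters",
    "analyze_region",
    "locate_somas",
]


@dataclass
class DensityConfig:
    """Gaussian kernel for the local density.

    ``sigma`` (um) should be slightly more than half the typical soma radius
    (4 um for ~7-10 um somas); the kernel window radius is fixed at
    ``R = 2 * sigma``.

    ``support`` selects the set the kernel sum runs over: ``"image"`` (default)
    sums the intensity of *every* voxel within the window — the density is
    then a smoothed image sampled at region points, robust even when the
    binarized region is porous at low SNR; ``"region"`` restricts the sum to
    the region's own foreground points.
    """

    sigma: float = 4.0
    support: str = "image"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.support not in ("image", "region"):
            raise ValueError("support must be 'image' or 'region'")

    @property
    def window_radius(self) -> float:
        return 2.0 * self.sigma


@dataclass
class CenterSelectConfig:
    """Automatic centre selection parameters.

    ``thre_selective`` is the maximum feature density of an isolated feature
    point (fraction of the region's points per smoothed feature bin);
    ``R_min`` (um) is the minimum estimated soma radius, which both gates the
    ``delta`` condition and sets the redundant-centre pruning distance.
    """

    thre_selective: float = 1e-2
    R_min: float = 3.0
    grid_width: float = 0.001
    window_size: int = 11
    kernel_width_grids: float = 3.0

    def __post_init__(self) -> None:
        if self.thre_selective <= 0 or self.R_min <= 0:
            raise ValueError("thre_selective and R_min must be positive")


def _rho_order(rho: np.ndarray, tiebreak: np.ndarray) -> np.ndarray:
    """Indices sorted by descending rho; ties broken by ascending tie-break key."""
    return np.lexsort((tiebreak, -rho))


def compute_rho(region: RegionPointSet, cfg: DensityConfig | None = None) -> np.ndarray:
    """Local density of every region point (region maximum normalised to 1).

    ``rho_i`` sums, over region points within Euclidean distance ``R = 2*sigma``
    of ``p_i`` (including ``p_i`` itself), the intensity ``I(p_j)`` weighted by
    a Gaussian kernel ``exp(-||p_i - p_j||^2 / (2 sigma^2)) / (sqrt(2 pi) sigma)``.
    The normalisation constant is the region's maximum raw sum, so
    ``max rho = 1`` and the (rho, delta) feature grid is bounded.
    """
    cfg = cfg or DensityConfig()
    pos = region.positions_um
    I = region.intensities
    sigma = cfg.sigma
    coef = 1.0 / (math.sqrt(2.0 * math.pi) * sigma)
    raw = I * coef  # self term, distance 0
    if len(region) > 1:
        tree = cKDTree(pos)
        pairs = tree.query_pairs(cfg.window_radius, output_type="ndarray")
        if len(pairs):
            i, j = pairs[:, 0], pairs[:, 1]
            d2 = np.einsum("ij,ij->i", pos[i] - pos[j], pos[i] - pos[j])
            w = coef * np.exp(-d2 / (2.0 * sigma**2))
            np.add.at(raw, i, I[j] * w)
            np.add.at(raw, j, I[i] * w)
    Z = raw.max()
    if Z <= 0:
        raise ValueError("region has non-positive density; check intensities")
    return raw / Z


def density_field(stack: VolumeStack, cfg: DensityConfig | None = None) -> np.ndarray:
    """Unnormalised local-density field over the whole stack.

    Convolves the intensity grid with the truncated Gaussian kernel
    ``exp(-d^2 / (2 sigma^2)) / (sqrt(2 pi) sigma)`` restricted to the
    spherical window ``d <= R = 2 sigma`` (physical distances; voxels outside
    the stack contribute 0).  Sampling this field at a region's points and
    dividing by the region maximum gives the image-supported ``rho``.
    """
    cfg = cfg or DensityConfig()
    sigma, R = cfg.sigma, cfg.window_radius
    vox = np.asarray(stack.voxel_size)
    half = np.ceil(R / vox).astype(int)
    grids = np.meshgrid(*[np.arange(-h, h + 1) * v for h, v in zip(half, vox)], indexing="ij")
    d2 = sum(g**2 for g in grids)
    kernel = np.exp(-d2 / (2.0 * sigma**2)) / (math.sqrt(2.0 * math.pi) * sigma)
    kernel[d2 > R**2] = 0.0
    from scipy.signal import fftconvolve

    field = fftconvolve(stack.data.astype(np.float64), kernel, mode="same")
    return np.maximum(field, 0.0)  # clip FFT ringing below zero


def compute_rho_image(
    region: RegionPointSet,
    field: np.ndarray,
) -> np.ndarray:
    """Image-supported local density of a region's points (region max = 1).

    ``field`` is the stack-wide density from :func:`density_field`; each
    region point takes the field value at its voxel, normalised by the region
    maximum.
    """
    raw = field[tuple(region.indices.T)]
    Z = raw.max()
    if Z <= 0:
        raise ValueError("region has non-positive density; check intensities")
    return raw / Z


def region_diameter(positions: np.ndarray) -> float:
    """Maximum pairwise Euclidean distance of a point set."""
    n = len(positions)
    if n < 2:
        return 0.0
    pts = positions
    if n > 500:
        try:  # diameter is attained on the convex hull
            from scipy.spatial import ConvexHull

            pts = positions[ConvexHull(positions).vertices]
        except Exception:  # degenerate (flat) point sets fall back to brute force
            pts = positions
    best = 0.0
    for k in range(0, len(pts), 256):
        chunk = pts[k : k + 256]
        d2 = ((chunk[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        best = max(best, float(d2.max()))
    return math.sqrt(best)


def compute_delta(
    region: RegionPointSet, rho: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Normalised minimum distance to a higher-density point, per point.

    For the region's unique density maximum ``delta = 1``; for every other
    point it is the distance to the nearest strictly-higher-``rho`` point
    divided by the region diameter.  Density ties are broken by ascending
    voxel order (the earlier voxel counts as higher), which makes the maximum
    unique.

    Returns ``(delta, nn_higher)`` where ``nn_higher[i]`` is the index of the
    nearest higher-density point (-1 for the maximum); the same link is used
    for cluster assignment.
    """
    n = len(region)
    pos = region.positions_um
    delta = np.empty(n)
    nn_higher = np.full(n, -1, dtype=np.int64)
    if n == 1:
        delta[0] = 1.0
        return delta, nn_higher
    order = _rho_order(rho, region.linear_indices)
    diam = region_diameter(pos)
    delta[order[0]] = 1.0
    sorted_pos = pos[order]
    for r in range(1, n):
        d2 = ((sorted_pos[:r] - sorted_pos[r]) ** 2).sum(-1)
        j = int(np.argmin(d2))
        idx = order[r]
        nn_higher[idx] = order[j]
        delta[idx] = math.sqrt(d2[j]) / diam
    return delta, nn_higher


def build_feature_image(
    rho: np.ndarray, delta: np.ndarray, cfg: CenterSelectConfig | None = None
) -> np.ndarray:
    """Smoothed 2D histogram of the (rho, delta) feature points.

    The grid covers ``(0, max rho]`` x ``(0, max delta]`` in 0.001-wide bins
    (``floor(1000 * max) + 1`` bins per axis); the count image is convolved
    with an 11 x 11 Gaussian window of width 3 grid units, normalised to unit
    sum, and divided by the number of points — so a bin's value is the
    (smoothed) fraction of the region's points whose features fall there.
    """
    cfg = cfg or CenterSelectConfig()
    n_r = int(np.floor(rho.max() / cfg.grid_width)) + 1
    n_d = int(np.floor(delta.max() / cfg.grid_width)) + 1
    br = np.minimum((rho / cfg.grid_width).astype(int), n_r - 1)
    bd = np.minimum((delta / cfg.grid_width).astype(int), n_d - 1)
    hist = np.zeros((n_r, n_d))
    np.add.at(hist, (br, bd), 1.0)
    half = cfg.window_size // 2
    off = np.arange(-half, half + 1)
    g = np.exp(-(off**2) / (2.0 * cfg.kernel_width_grids**2))
    kernel = np.outer(g, g)
    kernel /= kernel.sum()
    smoothed = ndimage.convolve(hist, kernel, mode="constant", cval=0.0)
    return smoothed / len(rho)


def feature_density(
    rho: np.ndarray, delta: np.ndarray, image: np.ndarray, cfg: CenterSelectConfig | None = None
) -> np.ndarray:
    """Feature density ``Lambda`` of each point: the smoothed-image value of
    the grid cell containing its (rho, delta) features (out-of-range features
    clamp to the edge bins)."""
    cfg = cfg or CenterSelectConfig()
    br = np.clip((rho / cfg.grid_width).astype(int), 0, image.shape[0] - 1)
    bd = np.clip((delta / cfg.grid_width).astype(int), 0, image.shape[1] - 1)
    return image[br, bd]


def select_candidates(
    delta: np.ndarray,
    Lambda: np.ndarray,
    diameter: float,
    cfg: CenterSelectConfig | None = None,
) -> np.ndarray:
    """Indices of candidate cluster centres.

    A point qualifies when it is isolated in feature space
    (``Lambda <= thre_selective``) and its minimum distance is at least the
    minimum soma radius (``delta >= R_min / diameter``).  Regions smaller than
    ``R_min`` across yield no candidates.
    """
    cfg = cfg or CenterSelectConfig()
    if diameter <= 0:
        return np.empty(0, dtype=np.int64)
    keep = (Lambda <= cfg.thre_selective) & (delta >= cfg.R_min / diameter)
    return np.flatnonzero(keep)


def prune_candidates(
    candidates: np.ndarray,
    positions: np.ndarray,
    rho: np.ndarray,
    tiebreak: np.ndarray,
    R_min: float,
) -> np.ndarray:
    """Delete redundant candidate centres closer than ``R_min`` to a stronger one.

    Candidates are traversed in descending-``rho`` order.  The current point
    (skipped if already labelled redundant) finds its nearest not-yet-traversed
    candidate; if that lies within ``R_min`` it is labelled redundant.
    Unlabelled candidates are the final centres, returned in traversal order.
    """
    candidates = np.asarray(candidates, dtype=np.int64)
    k = len(candidates)
    if k <= 1:
        return candidates.copy()
    order = _rho_order(rho[candidates], tiebreak[candidates])
    cand = candidates[order]
    pos = positions[cand]
    labeled = np.zeros(k, dtype=bool)
    for t in range(k - 1):
        if labeled[t]:
            continue
        rest = np.arange(t + 1, k)
        d2 = ((pos[rest] - pos[t]) ** 2).sum(-1)
        j = rest[int(np.argmin(d2))]
        if math.sqrt(d2.min()) < R_min:
            labeled[j] = True
    return cand[~labeled]


def assign_clusters(
    region: RegionPointSet,
    rho: np.ndarray,
    nn_higher: np.ndarray,
    centers: np.ndarray,
) -> np.ndarray:
    """Assign every region point to a centre's cluster.

    Centres get labels ``0..c-1``; the remaining points, visited in
    descending-``rho`` passes, take the label of their nearest higher-density
    point once that point is labelled, re-queueing until no progress is made.
    Points that can never inherit a label along their higher-density link
    (possible only when the region's density maximum is not a centre) fall
    back to the label of the nearest labelled point.  Returns -1 for all
    points when ``centers`` is empty.
    """
    n = len(region)
    labels = np.full(n, -1, dtype=np.int64)
    centers = np.asarray(centers, dtype=np.int64)
    if len(centers) == 0:
        return labels
    labels[centers] = np.arange(len(centers))
    order = _rho_order(rho, region.linear_indices)
    queue = [i for i in order if labels[i] < 0]
    while queue:
        progressed = False
        next_queue = []
        for i in queue:
            j = nn_higher[i]
            if j >= 0 and labels[j] >= 0:
                labels[i] = labels[j]
                progressed = True
            else:
                next_queue.append(i)
        queue = next_queue
        if not progressed:
            break
    if queue:  # unreachable roots: nearest labelled point decides
        pos = region.positions_um
        labeled_idx = np.flatnonzero(labels >= 0)
        tree = cKDTree(pos[labeled_idx])
        _, nn = tree.query(pos[queue])
        labels[np.asarray(queue)] = labels[labeled_idx[nn]]
    return labels


@dataclass
class RegionFeatures:
    """Per-region clustering diagnostics (the decision-graph quantities)."""

    region_id: int
    rho: np.ndarray
    delta: np.ndarray
    Lambda: np.ndarray
    diameter: float
    candidates: np.ndarray
    centers: np.ndarray
    labels: np.ndarray


def analyze_region(
    region: RegionPointSet,
    density_cfg: DensityConfig | None = None,
    select_cfg: CenterSelectConfig | None = None,
    field: np.ndarray | None = None,
) -> RegionFeatures:
    """Run the full per-region chain: rho, delta, Lambda, candidates, centres, labels.

    ``field`` is the precomputed stack-wide density (required for
    ``support="image"``); with ``support="region"`` the density is built from
    the region's own points.
    """
    density_cfg = density_cfg or DensityConfig()
    select_cfg = select_cfg or CenterSelectConfig()
    if density_cfg.support == "image":
        if field is None:
            raise ValueError("image-supported density needs the precomputed field")
        rho = compute_rho_image(region, field)
    else:
        rho = compute_rho(region, density_cfg)
    delta, nn_higher = compute_delta(region, rho)
    diam = region_diameter(region.positions_um)
    image = build_feature_image(rho, delta, select_cfg)
    Lambda = feature_density(rho, delta, image, select_cfg)
    candidates = select_candidates(delta, Lambda, diam, select_cfg)
    centers = prune_candidates(
        candidates, region.positions_um, rho, region.linear_indices, select_cfg.R_min
    )
    labels = assign_clusters(region, rho, nn_higher, centers)
    return RegionFeatures(
        region_id=region.region_id,
        rho=rho,
        delta=delta,
        Lambda=Lambda,
        diameter=diam,
        candidates=candidates,
        centers=centers,
        labels=labels,
    )


def locate_somas(
    stack: VolumeStack,
    regions: list[RegionPointSet],
    density_cfg: DensityConfig | None = None,
    select_cfg: CenterSelectConfig | None = None,
) -> tuple[list[SomaDetection], np.ndarray]:
    """Locate and segment somas in every region of a stack.

    Returns the detections (centre = the cluster-centre voxel's position, in
    um) and an int32 label map aligned with the stack, 0 = background and
    labels 1..N one per detection, globally unique across regions.
    """
    density_cfg = density_cfg or DensityConfig()
    select_cfg = select_cfg or CenterSelectConfig()
    detections: list[SomaDetection] = []
    label_map = np.zeros(stack.shape, dtype=np.int32)
    next_label = 1
    field = density_field(stack, density_cfg) if density_cfg.support == "image" else None
    for region in regions:
        # a region narrower than R_min across cannot satisfy the delta
        # condition (delta <= 1 < R_min / diameter), so it yields no centres;
        # the bounding-box diagonal is a cheap upper bound on the diameter
        span = (region.positions_um.max(0) - region.positions_um.min(0)) if len(region) > 1 else 0.0
        if len(region) == 1 or float(np.linalg.norm(span)) < select_cfg.R_min:
            continue
        feats = analyze_region(region, density_cfg, select_cfg, field=field)
        for c_local, center_idx in enumerate(feats.centers):
            members = np.flatnonzero(feats.labels == feats.labels[center_idx])
            det = SomaDetection(
                center_um=region.positions_um[center_idx],
                region_id=region.region_id,
                label=next_label,
                member_indices=region.indices[members],
                member_positions_um=region.positions_um[members],
                member_intensities=region.intensities[members],
            )
            label_map[tuple(region.indices[members].T)] = next_label
            detections.append(det)
            next_label += 1
    return detections, label_map
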