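"""Drivers for the touching-pair simulation study.

These helpers run the full pipeline on sphere-pair phantoms and score the
outcome: a pair counts as *correctly split* when the pipeline returns exactly
two detections and each lies within the match threshold (8 um) of a distinct
true centre.  They are used both by the test suite and by the acceptance
script, so the study conditions (radius 10 um, I_b = 100, the d and SNR
grids) live in one place.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np

from .evaluation import match
from .phantom import DEFAULT_D_GRID, generate_stack, pair_spec
from .pipeline import RunConfig, run_pipeline
from .preprocess import extract_regions
from .density_peaks import locate_somas

__all__ = [
    "split_correctly",
    "split_success_count",
    "smallest_split_distance",
    "sigma_effective_set",
]


def split_correctly(
    truth_centers: np.ndarray,
    pred_centers: np.ndarray,
    threshold_um: float = 8.0,
) -> bool:
    """True when exactly two predictions each match a distinct true centre."""
    pred_centers = np.asarray(pred_centers).reshape(-1, 3)
    if len(pred_centers) != 2:
        return False
    return len(match(truth_centers, pred_centers, threshold_um)) == 2


def _run_pair(snr: float, d: float, seed, config: RunConfig) -> tuple[np.ndarray, np.ndarray]:
    spec = pair_spec(snr, d, seed=seed)
    stack, truth = generate_stack(spec)
    result = run_pipeline(stack, config)
    return truth.centers_um, result.centers_um


def split_success_count(
    snr: float,
    d: float,
    seeds: Sequence,
    config: RunConfig | None = None,
) -> int:
    """Number of seeds for which the (snr, d) pair is correctly split."""
    config = config or RunConfig.simulation()
    wins = 0
    for seed in seeds:
        truth, pred = _run_pair(snr, d, seed, config)
        if split_correctly(truth, pred, config.match_threshold_um):
            wins += 1
    return wins


def smallest_split_distance(
    snr: float,
    base_seed: int,
    d_grid: Sequence[float] = DEFAULT_D_GRID,
    n_seeds: int = 10,
    min_wins: int = 6,
    config: RunConfig | None = None,
) -> float | None:
    """Smallest pair distance the pipeline splits for a majority of seeds.

    For each ``d`` in ascending order, the pair phantom is generated and
    analysed under ``n_seeds`` independent noise realisations (streams derived
    from ``(base_seed, seed index, snr, d)``); ``d`` qualifies when at least
    ``min_wins`` realisations are correctly split.  Returns the smallest
    qualifying ``d`` (None if none qualifies).
    """
    config = config or RunConfig.simulation()
    for d in sorted(d_grid):
        seeds = [[int(base_seed), s, int(round(10 * snr)), int(round(d))] for s in range(n_seeds)]
        if split_success_count(snr, d, seeds, config) >= min_wins:
            return float(d)
    return None


def sigma_effective_set(
    snr: float = 3.0,
    d: float = 14.0,
    seed=0,
    sigma_grid: Sequence[float] = tuple(np.arange(0.5, 15.1, 0.5)),
    config: RunConfig | None = None,
) -> list[float]:
    """Kernel widths for which one pair phantom is correctly localized.

    Generates a single (snr, d) phantom, preprocesses it once, then sweeps
    the density kernel width; a ``sigma`` is effective when exactly two
    detections each lie within the match threshold of a distinct true centre.
    """
    config = config or RunConfig.simulation()
    spec = pair_spec(snr, d, seed=seed)
    stack, truth = generate_stack(spec)
    base = run_pipeline(stack, config)  # preprocessing is sigma-independent
    regions = [
        r
        for r in extract_regions(base.mask, stack)
        if len(r) >= config.min_region_voxels
    ]
    effective = []
    for sigma in sigma_grid:
        cfg = replace(config, sigma_um=float(sigma))
        dets, _ = locate_somas(stack, regions, cfg.density_config(), cfg.select_config())
        centers = np.array([dd.center_um for dd in dets]) if dets else np.empty((0, 3))
        if split_correctly(truth.centers_um, centers, config.match_threshold_um):
            effective.append(float(sigma))
    return effective
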