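"""End-to-end soma localization: preprocessing, clustering, morphometrics.

Two parameter presets cover the two regimes the method targets:

* :func:`RunConfig.simulation` — low-contrast data without neurites
  (``thre_binarization = 2``): background speckle is removed with a light
  despeckle pass and a minimum-region-volume floor; the iterated erosion is
  off because it would destroy the porous foreground such data produces.
* :func:`RunConfig.experimental` — bright somas with neurites and artifacts
  (``thre_binarization = 6``): the iterated neighbourhood-count erosion
  removes thin structures from the (solid) binarized mask.

The pipeline is deterministic: a fixed input stack and configuration always
produce identical detections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .density_peaks import CenterSelectConfig, DensityConfig, locate_somas
from .morphometry import morphometry_table
from .preprocess import (
    BinarizeConfig,
    ErosionConfig,
    binarize,
    despeckle,
    erode,
    estimate_background,
    extract_regions,
    merge_blocks,
    split_blocks,
)
from .types import SomaDetection, VolumeStack

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "detections_table"]


@dataclass
class RunConfig:
    """All pipeline tunables, with defaults for low-contrast (simulation-like) data.

    Attributes
    ----------
    thre_binarization
        Poisson-sigma threshold of the binarization rule (2 for low-contrast,
        6 for bright experimental signal).
    apply_erosion / erosion
        Whether to run the iterated neighbourhood-count erosion and its
        schedule; meant for solid masks with neurites or artifacts.
    apply_despeckle / despeckle_T / despeckle_passes
        Light noise removal for porous masks: drop foreground voxels with
        fewer than ``despeckle_T`` foreground voxels in their 3x3x3
        neighbourhood, repeated ``despeckle_passes`` times.
    min_region_voxels
        Discard 26-connected regions smaller than this many voxels (guards
        against residual background speckle; ~10% of the smallest soma's
        volume is a safe floor).
    sigma_um
        Gaussian kernel width of the local density (window radius ``2*sigma``).
    R_min_um
        Minimum estimated soma radius: gates the minimum-distance condition
        and the redundant-centre pruning.
    thre_selective
        Feature-density ceiling for candidate centres.
    block_size / overlap
        Sub-block layout for large stacks.
    """

    thre_binarization: float = 2.0
    apply_erosion: bool = False
    erosion: ErosionConfig = field(default_factory=ErosionConfig)
    apply_despeckle: bool = True
    despeckle_T: float = 4.0
    despeckle_passes: int = 2
    min_region_voxels: int = 52
    sigma_um: float = 4.0
    density_support: str = "image"
    R_min_um: float = 8.0
    thre_selective: float = 1e-2
    block_size: int = 200
    overlap: int = 12
    match_threshold_um: float = 8.0

    @classmethod
    def simulation(cls) -> "RunConfig":
        """Preset for synthetic/low-contrast neurite-free stacks (the default)."""
        return cls()

    @classmethod
    def experimental(cls) -> "RunConfig":
        """Preset for bright experimental stacks with neurites/artifacts."""
        return cls(
            thre_binarization=6.0,
            apply_erosion=True,
            apply_despeckle=False,
            min_region_voxels=2,
            R_min_um=3.0,
        )

    def binarize_config(self) -> BinarizeConfig:
        return BinarizeConfig(thre_binarization=self.thre_binarization)

    def density_config(self) -> DensityConfig:
        return DensityConfig(sigma=self.sigma_um, support=self.density_support)

    def select_config(self) -> CenterSelectConfig:
        return CenterSelectConfig(thre_selective=self.thre_selective, R_min=self.R_min_um)

    def as_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class PipelineResult:
    """Everything a run produces: detections, label map, mask, stage report."""

    detections: list[SomaDetection]
    label_map: np.ndarray
    mask: np.ndarray
    report: dict

    @property
    def centers_um(self) -> np.ndarray:
        if not self.detections:
            return np.empty((0, 3))
        return np.array([d.center_um for d in self.detections])


def run_pipeline(stack: VolumeStack, config: RunConfig | None = None) -> PipelineResult:
    """Locate and segment somas in a stack.

    Stages: block split -> background estimate -> binarize ->
    (despeckle and/or erode) -> merge -> 26-connected regions ->
    per-region density-peak clustering.  The report collects per-stage counts
    (foreground voxels, regions, detections).
    """
    config = config or RunConfig()
    bin_cfg = config.binarize_config()
    layout, blocks = split_blocks(stack, block_size=config.block_size, overlap=config.overlap)
    block_masks = []
    fg_binarized = 0
    for block in blocks:
        C = estimate_background(block, bin_cfg)
        bm = binarize(block, C, bin_cfg)
        fg_binarized += int(bm.sum())
        if config.apply_despeckle:
            bm = despeckle(bm, T=config.despeckle_T, passes=config.despeckle_passes)
        if config.apply_erosion:
            bm = erode(bm, config.erosion)
        block_masks.append(bm)
    mask = merge_blocks(block_masks, layout)
    regions = extract_regions(mask, stack)
    n_regions_all = len(regions)
    regions = [r for r in regions if len(r) >= config.min_region_voxels]
    detections, label_map = locate_somas(
        stack, regions, config.density_config(), config.select_config()
    )
    report = {
        "n_blocks": layout.n_blocks,
        "foreground_voxels_binarized": fg_binarized,
        "foreground_voxels_final": int(mask.sum()),
        "n_regions": n_regions_all,
        "n_regions_kept": len(regions),
        "n_detections": len(detections),
        "config": config.as_dict(),
    }
    logger.info(
        "pipeline: %d blocks, %d fg voxels (%d after cleanup), %d regions "
        "(%d kept), %d detections",
        layout.n_blocks, fg_binarized, report["foreground_voxels_final"],
        n_regions_all, len(regions), len(detections),
    )
    return PipelineResult(detections=detections, label_map=label_map, mask=mask, report=report)


def detections_table(
    result: PipelineResult,
    stack: VolumeStack,
    with_morphometry: bool = True,
) -> pd.DataFrame:
    """Detections as a DataFrame (x/y/z in um and voxel indices, one row per soma)."""
    dets = result.detections
    vox = np.asarray(stack.voxel_size)
    centers = result.centers_um
    idx = (centers / vox - 0.5).round().astype(int) if len(dets) else np.empty((0, 3), int)
    df = pd.DataFrame(
        {
            "label": [d.label for d in dets],
            "region_id": [d.region_id for d in dets],
            "x_um": centers[:, 2] if len(dets) else [],
            "y_um": centers[:, 1] if len(dets) else [],
            "z_um": centers[:, 0] if len(dets) else [],
            "x_idx": idx[:, 2] if len(dets) else [],
            "y_idx": idx[:, 1] if len(dets) else [],
            "z_idx": idx[:, 0] if len(dets) else [],
            "n_voxels": [d.n_voxels for d in dets],
        }
    )
    if with_morphometry and dets:
        morph = morphometry_table(dets, stack)
        df = df.merge(morph.drop(columns=["n_voxels"]), on="label")
    return df
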