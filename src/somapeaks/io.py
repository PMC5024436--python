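"""Reading and writing stacks, masks, detection tables and configurations.

Stacks travel as multi-page grayscale TIFF (page order = z); the voxel size
is supplied by the caller or a config file, since TIFF metadata is unreliable
in practice.  Detections and ground truth are CSV with ``x_um, y_um, z_um``
columns (note: arrays in memory are indexed ``z, y, x``; the CSV column order
is the human-friendly convention).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .phantom import GroundTruth
from .pipeline import RunConfig
from .types import VolumeStack

__all__ = [
    "read_stack",
    "write_stack",
    "write_label_map",
    "write_truth_csv",
    "read_truth_csv",
    "read_centers_csv",
    "load_config",
    "save_config",
]


def read_stack(
    path: str | Path, voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
) -> VolumeStack:
    """Read a grayscale multi-page TIFF as a :class:`VolumeStack`.

    ``voxel_size`` is ``(z, y, x)`` in micrometres.  RGB or otherwise
    non-grayscale files are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack: {path}")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(
            f"{path.name}: expected a grayscale z-stack, got shape {data.shape} "
            "(RGB or multi-channel TIFFs are not supported)"
        )
    if not np.issubdtype(data.dtype, np.integer) and not np.issubdtype(data.dtype, np.floating):
        raise ValueError(f"{path.name}: unsupported dtype {data.dtype}")
    return VolumeStack(data=data, voxel_size=voxel_size)


def write_stack(path: str | Path, stack: VolumeStack) -> None:
    """Write a stack as multi-page TIFF (page order = z), preserving dtype."""
    tifffile.imwrite(Path(path), stack.data)


def write_label_map(path: str | Path, label_map: np.ndarray) -> None:
    """Write a 32-bit label map as multi-page TIFF (0 = background)."""
    tifffile.imwrite(Path(path), label_map.astype(np.int32))


def write_truth_csv(path: str | Path, truth: GroundTruth) -> None:
    """Ground-truth centres/radii as CSV (x_um, y_um, z_um, radius_um)."""
    c = truth.centers_um
    pd.DataFrame(
        {"x_um": c[:, 2], "y_um": c[:, 1], "z_um": c[:, 0], "radius_um": truth.radii_um}
    ).to_csv(Path(path), index=False)


def read_truth_csv(path: str | Path) -> GroundTruth:
    df = pd.read_csv(Path(path))
    centers = df[["z_um", "y_um", "x_um"]].to_numpy(dtype=float)
    radii = df["radius_um"].to_numpy(dtype=float) if "radius_um" in df else np.full(len(df), np.nan)
    return GroundTruth(centers_um=centers, radii_um=radii)


def read_centers_csv(path: str | Path) -> np.ndarray:
    """Read centre positions from any CSV with x_um/y_um/z_um columns -> (n, 3) (z, y, x)."""
    df = pd.read_csv(Path(path))
    missing = [c for c in ("x_um", "y_um", "z_um") if c not in df]
    if missing:
        raise ValueError(f"{Path(path).name}: missing columns {missing}")
    return df[["z_um", "y_um", "x_um"]].to_numpy(dtype=float)


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`~somapeaks.pipeline.RunConfig` from YAML (unknown keys rejected)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    erosion = raw.pop("erosion", None)
    cfg = RunConfig(**raw)
    if erosion:
        from .preprocess import ErosionConfig

        cfg.erosion = ErosionConfig(**erosion)
    return cfg


def save_config(path: str | Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.as_dict(), fh, sort_keys=False)
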