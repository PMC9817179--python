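"""File I/O helpers: TIFF stacks and masks, trajectory CSVs, mask series."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .puncta import NucleusMask, NucleusStack
from .spt import MaskSeries

__all__ = [
    "read_stack",
    "read_mask",
    "write_stack",
    "read_mask_series",
    "read_pairing_manifest",
]


def read_stack(path) -> NucleusStack:
    """Multi-page grayscale TIFF z-stack -> NucleusStack."""
    arr = tifffile.imread(str(path))
    return NucleusStack(np.asarray(arr, dtype=float))


def read_mask(path) -> NucleusMask:
    """Single-page TIFF/PNG mask; any nonzero pixel counts as inside."""
    p = str(path)
    if p.lower().endswith((".tif", ".tiff")):
        arr = tifffile.imread(p)
    else:
        from imageio.v3 import imread

        arr = imread(p)
    if arr.ndim == 3:  # drop a color axis if present
        arr = arr[..., 0] if arr.shape[-1] in (3, 4) else arr[0]
    return NucleusMask(np.asarray(arr) != 0)


def write_stack(path, stack: NucleusStack | np.ndarray) -> None:
    arr = stack.voxels if isinstance(stack, NucleusStack) else np.asarray(stack)
    tifffile.imwrite(str(path), arr.astype(np.float32))


def read_mask_series(mask_dir, times_csv) -> MaskSeries:
    """Numbered TIFF mask frames plus a CSV with columns (frame_file, time_s)."""
    df = pd.read_csv(times_csv)
    masks = [tifffile.imread(str(Path(mask_dir) / f)) != 0 for f in df["frame_file"]]
    return MaskSeries(times=df["time_s"].to_numpy(float), masks=np.stack(masks))


def read_pairing_manifest(path) -> pd.DataFrame:
    """Manifest CSV: cell_id, live_path, fixed_path, mask_live, mask_fixed."""
    df = pd.read_csv(path)
    required = {"cell_id", "live_path", "fixed_path", "mask_live", "mask_fixed"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pairing manifest missing columns: {sorted(missing)}")
    return df
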