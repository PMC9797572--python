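"""Readers and writers for the pipeline's on-disk formats.

The infection-matrix dialect is a CSV with phage isolate ids as the header
column, bacterial isolate ids as the header row, and empty cells for
missing (unmeasured) pairs.  Time-lapse stacks are read from a multi-page
TIFF or a globbed series of single-frame images.
"""

from __future__ import annotations

import glob
import os

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile


def read_infection_matrix(path) -> pd.DataFrame:
    """Read the CSV infectivity matrix (phage rows x bacteria columns)."""
    df = pd.read_csv(path, index_col=0)
    df.index.name = "phage_id"
    df.columns.name = "bacterium_id"
    vals = df.to_numpy(float)
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise ValueError("infectivity scores must lie in [0, 1]")
    return df


def write_infection_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, na_rep="")


def read_stack(path_or_pattern: str) -> np.ndarray:
    """Read a T x H x W (or T x H x W x C) stack.

    Accepts a multi-page TIFF path, a directory of frames, or a glob
    pattern; series frames are stacked in sorted filename order.
    """
    if os.path.isdir(path_or_pattern):
        files = sorted(
            f for f in glob.glob(os.path.join(path_or_pattern, "*"))
            if f.lower().endswith((".png", ".jpg", ".jpeg", ".tif", ".tiff"))
        )
    elif any(ch in path_or_pattern for ch in "*?["):
        files = sorted(glob.glob(path_or_pattern))
    else:
        return tifffile.imread(path_or_pattern)
    if not files:
        raise FileNotFoundError(f"no frames match {path_or_pattern!r}")
    return np.stack([iio.imread(f) for f in files])


def write_stack(stack: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(stack))


def write_dominance_map(dmap, tiff_path, csv_path) -> None:
    """Write a dominance map as a 3-layer float TIFF plus a tidy CSV."""
    layers = np.stack(
        [dmap.eta_final, dmap.eta_diff, dmap.cycle_count.astype(float)]
    )
    tifffile.imwrite(tiff_path, layers.astype(np.float32))
    nh, nw = dmap.cycle_count.shape
    rr, cc = np.meshgrid(np.arange(nh), np.arange(nw), indexing="ij")
    pd.DataFrame(
        {
            "block_row": rr.ravel(),
            "block_col": cc.ravel(),
            "eta_final": dmap.eta_final.ravel(),
            "eta_diff": dmap.eta_diff.ravel(),
            "cycles": dmap.cycle_count.ravel(),
        }
    ).to_csv(csv_path, index=False)
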