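"""Mask-based single-cell quantification.

Turns a multi-channel intensity image plus an integer label mask into a
cell table: one row per segmented cell with mean marker intensities,
centroid and area. Images are channel-first (C, H, W) with channel order
equal to the panel order; masks are single-channel with 0 = background.
Coordinates are 0-based with x = column, y = row.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.measure import regionprops_table

__all__ = ["quantify_image", "merge_images", "ID_COLS"]

#: identity / geometry columns of a cell table, before the marker columns
ID_COLS = ["cell_id", "image_id", "patient_id", "batch", "x", "y", "area_px"]


def quantify_image(
    image: np.ndarray,
    mask: np.ndarray,
    panel: list[str],
    image_id: str,
    patient_id: str,
    batch: str,
) -> pd.DataFrame:
    """Per-cell mean intensity of every channel over the cell's pixels.

    Labels need not be consecutive; every positive label yields exactly
    one row. Raises on image/mask shape mismatch or panel/channel
    count mismatch.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.ndim != 3:
        raise ValueError("image must be (channels, height, width)")
    if image.shape[1:] != mask.shape:
        raise ValueError(f"image {image.shape[1:]} and mask {mask.shape} dimensions differ")
    if image.shape[0] != len(panel):
        raise ValueError(f"panel has {len(panel)} markers but image has {image.shape[0]} channels")
    if mask.max() == 0:
        return pd.DataFrame(columns=ID_COLS + list(panel))
    props = regionprops_table(
        mask.astype(np.int64),
        intensity_image=np.moveaxis(image, 0, -1),
        properties=("label", "area", "centroid", "intensity_mean"),
    )
    n = len(props["label"])
    out = pd.DataFrame(
        {
            "cell_id": props["label"].astype(int),
            "image_id": image_id,
            "patient_id": patient_id,
            "batch": batch,
            "x": props["centroid-1"],  # column
            "y": props["centroid-0"],  # row
            "area_px": props["area"].astype(int),
        }
    )
    for c, marker in enumerate(panel):
        key = f"intensity_mean-{c}" if n and f"intensity_mean-{c}" in props else "intensity_mean"
        out[marker] = props[key]
    return out


def merge_images(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-image cell tables; cells from different images of
    the same tumor are merged before any patient-level analysis.

    (image_id, cell_id) must be globally unique across inputs.
    """
    if not tables:
        raise ValueError("no tables to merge")
    merged = pd.concat(tables, ignore_index=True)
    dup = merged.duplicated(subset=["image_id", "cell_id"])
    if dup.any():
        raise ValueError("duplicate (image_id, cell_id) keys in merge")
    return merged
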