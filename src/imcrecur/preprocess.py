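"""Intensity preprocessing: acquisition-batch correction and arcsinh
transformation.

Batch correction is quantile-anchored affine rescaling ("range"
correction): per marker, an affine map sends each batch's trimmed
intensity range — its (q_low, q_high) quantiles — onto the reference
range (pooled data by default). Applied on raw intensities before the
arcsinh transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from imcrecur.markers import ASINH_PREFIX

__all__ = ["PreprocessConfig", "range_batch_correct", "arcsinh_transform"]


@dataclass
class PreprocessConfig:
    cofactor: float = 5.0
    q_low: float = 0.01
    q_high: float = 0.99
    reference_batch: str = "pooled"

    def __post_init__(self):
        if self.cofactor <= 0:
            raise ValueError("cofactor must be positive")
        if not (0 < self.q_low < self.q_high < 1):
            raise ValueError("need 0 < q_low < q_high < 1")


def range_batch_correct(
    cells: pd.DataFrame,
    markers: list[str],
    config: PreprocessConfig | None = None,
) -> pd.DataFrame:
    """Affine-align each batch's (q_low, q_high) intensity quantiles to the
    reference per marker; corrected intensities are clipped at 0.

    A degenerate batch (equal anchor quantiles) is left unchanged with a
    warning. Returns a corrected copy of the table.
    """
    config = config or PreprocessConfig()
    out = cells.copy()
    batches = out["batch"].unique()
    counts = out["batch"].value_counts()
    if (counts < 2).any():
        raise ValueError("every batch needs at least 2 cells")
    qs = (config.q_low, config.q_high)
    for m in markers:
        if config.reference_batch == "pooled":
            ref_lo, ref_hi = np.quantile(out[m].to_numpy(), qs)
        else:
            ref = out.loc[out["batch"] == config.reference_batch, m]
            if ref.empty:
                raise ValueError(f"reference batch {config.reference_batch!r} not found")
            ref_lo, ref_hi = np.quantile(ref.to_numpy(), qs)
        for b in batches:
            sel = out["batch"] == b
            lo, hi = np.quantile(out.loc[sel, m].to_numpy(), qs)
            if hi - lo <= 0:
                warnings.warn(
                    f"batch {b!r}, marker {m!r}: degenerate quantile range; identity applied"
                )
                continue
            scale = (ref_hi - ref_lo) / (hi - lo)
            out.loc[sel, m] = np.clip((out.loc[sel, m] - lo) * scale + ref_lo, 0.0, None)
    return out


def arcsinh_transform(
    cells: pd.DataFrame, markers: list[str], cofactor: float = 5.0
) -> pd.DataFrame:
    """Add arcsinh(intensity / cofactor) columns (prefix ``asinh_``).

    The transform is strictly increasing and invertible; cofactor 5 is
    the mass-cytometry convention.
    """
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    out = cells.copy()
    vals = np.arcsinh(out[markers].to_numpy(dtype=float) / cofactor)
    for j, m in enumerate(markers):
        out[ASINH_PREFIX + m] = vals[:, j]
    return out
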