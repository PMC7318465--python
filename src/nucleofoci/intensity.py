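"""Per-nucleus channel intensities and Z-score standardisation.

Intensities are measured through the nuclear overlay mask only (background
pixels never contribute).  For cross-condition comparisons each channel's
per-nucleus values are converted to Z-scores over a common pool, putting
different proteins on the same dimensionless scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_io import ImageField, InputError
from .segmentation import NucleusLabelMap

__all__ = ["nuclear_intensity", "zscore", "zscore_table"]


def nuclear_intensity(field: ImageField, nuclei: NucleusLabelMap) -> pd.DataFrame:
    """Measure every channel inside every nucleus of the label map.

    Returns one row per (nucleus, channel) with ``mean_intensity``,
    ``integrated_intensity`` (sum over nucleus pixels) and ``area_um2``.
    """
    labels = nuclei.labels
    if labels.shape != field.shape:
        raise InputError("label map and field shapes differ")
    n = int(labels.max(initial=0))
    if n == 0:
        return pd.DataFrame(columns=[
            "field_id", "nucleus_id", "channel", "mean_intensity",
            "integrated_intensity", "n_pixels", "area_um2"])
    index = np.arange(1, n + 1)
    n_pixels = ndimage.sum_labels(np.ones_like(labels), labels, index)
    if np.any(n_pixels == 0):
        raise RuntimeError("empty nucleus label encountered")
    rows = []
    for channel, image in field.channels.items():
        sums = ndimage.sum_labels(np.asarray(image, dtype=float), labels, index)
        for nid, s, npx in zip(index, sums, n_pixels):
            rows.append({
                "field_id": field.field_id,
                "nucleus_id": int(nid),
                "channel": channel,
                "mean_intensity": s / npx,
                "integrated_intensity": s,
                "n_pixels": int(npx),
                "area_um2": npx * field.pixel_area_um2,
            })
    return pd.DataFrame(rows)


def zscore(values, ddof: int = 1) -> np.ndarray:
    """Standardise values to mean 0, sd 1 (``ddof`` divisor).

    Raises on fewer than two values or zero spread, where the Z-score is
    undefined.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise InputError("zscore expects a 1-D sequence")
    if x.size < 2:
        raise InputError("zscore needs at least two values")
    sd = x.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise InputError("zscore undefined for constant input")
    return (x - x.mean()) / sd


def zscore_table(
    intensity: pd.DataFrame,
    value: str = "integrated_intensity",
    ddof: int = 1,
    scope: str = "experiment",
) -> pd.DataFrame:
    """Z-score a per-nucleus intensity table channel by channel.

    All nuclei of all conditions within one table form the standardisation
    pool for each channel (a common scale is what makes between-protein and
    between-condition comparisons meaningful).  ``grouping_scope`` records
    the pool identity in the output.
    """
    if value not in intensity.columns:
        raise InputError(f"column {value!r} not in intensity table")
    out = intensity.copy()
    out["z"] = np.nan
    for channel, idx in out.groupby("channel").groups.items():
        out.loc[idx, "z"] = zscore(out.loc[idx, value].to_numpy(), ddof=ddof)
    out["grouping_scope"] = f"{scope}:per-channel"
    return out
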