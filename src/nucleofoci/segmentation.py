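"""Nuclei segmentation from the DAPI channel.

Fixed dynamic-range thresholding produces the nuclear binary mask; connected
components become candidate nuclei; candidates are rejected by size (area in
μm²), shape (circularity 4πA/P²) and border contact, mirroring a
particle-analyzer workflow with size/shape false-positive filters.  The
surviving label map is the overlay mask every downstream measurement is
restricted to.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .image_io import ImageField, InputError, PipelineConfig

logger = logging.getLogger("nucleofoci")


@dataclass
class NucleusLabelMap:
    """Labelled nuclei: 0 = background, k > 0 = nucleus k (consecutive)."""

    labels: np.ndarray
    field_id: str = ""

    @property
    def n_nuclei(self) -> int:
        return int(self.labels.max(initial=0))


@dataclass
class NucleusRecord:
    """One segmented nucleus and its per-channel measurements."""

    nucleus_id: int
    centroid_rc: tuple[float, float]
    area_um2: float
    circularity: float
    touches_border: bool
    mean_intensity: dict[str, float] = field(default_factory=dict)
    integrated_intensity: dict[str, float] = field(default_factory=dict)
    focus_count: int = 0


def threshold_fixed(image: np.ndarray, threshold_fraction: float) -> np.ndarray:
    """Binary mask at a fixed fraction of the image's dynamic range.

    A pixel is foreground iff
    ``intensity >= min + threshold_fraction * (max - min)``, so uint8, uint16
    and float inputs behave identically.  A constant image yields an empty
    mask with a logged warning.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise InputError("threshold_fraction must lie strictly in (0, 1)")
    image = np.asarray(image, dtype=float)
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        logger.warning("constant image: fixed threshold yields empty mask")
        return np.zeros(image.shape, dtype=bool)
    cutoff = lo + threshold_fraction * (hi - lo)
    return image >= cutoff


def label_components(mask: np.ndarray, connectivity: int = 8,
                     field_id: str = "") -> NucleusLabelMap:
    """Label maximal connected foreground components 1..K."""
    if connectivity not in (4, 8):
        raise InputError("connectivity must be 4 or 8")
    labels = measure.label(np.asarray(mask, dtype=bool),
                           connectivity=1 if connectivity == 4 else 2)
    return NucleusLabelMap(labels=labels, field_id=field_id)


def _circularity(area_px: float, perimeter_px: float) -> float:
    # clamp at 1: digitised discs can exceed 1 through perimeter underestimation
    if perimeter_px <= 0:
        return 1.0
    return min(1.0, 4.0 * np.pi * area_px / perimeter_px**2)


def filter_nuclei(
    label_map: NucleusLabelMap,
    dapi: np.ndarray,
    cfg: PipelineConfig,
    pixel_size_um: float,
) -> tuple[NucleusLabelMap, list[NucleusRecord]]:
    """Reject false-positive nuclei by size, shape and border contact.

    Components with area outside ``cfg.nucleus_area_range_um2``, circularity
    outside ``cfg.nucleus_circularity_range``, or touching the field border
    (when ``cfg.exclude_border``) are removed; survivors are relabelled
    consecutively 1..K' in original label order and one :class:`NucleusRecord`
    is emitted per survivor (DAPI intensities filled, ``focus_count`` 0).
    """
    labels = label_map.labels
    dapi = np.asarray(dapi, dtype=float)
    if labels.shape != dapi.shape:
        raise InputError("label map and DAPI image shapes differ")
    px_area = pixel_size_um**2
    lo_a, hi_a = cfg.nucleus_area_range_um2
    lo_c, hi_c = cfg.nucleus_circularity_range
    nrows, ncols = labels.shape

    new_labels = np.zeros_like(labels)
    records: list[NucleusRecord] = []
    next_id = 1
    for prop in measure.regionprops(labels, intensity_image=dapi):
        area_um2 = prop.area * px_area
        circ = _circularity(prop.area, prop.perimeter)
        r0, c0, r1, c1 = prop.bbox
        touches = r0 == 0 or c0 == 0 or r1 == nrows or c1 == ncols
        if not lo_a <= area_um2 <= hi_a:
            continue
        if not lo_c <= circ <= hi_c:
            continue
        if cfg.exclude_border and touches:
            continue
        new_labels[labels == prop.label] = next_id
        records.append(NucleusRecord(
            nucleus_id=next_id,
            centroid_rc=(float(prop.centroid[0]), float(prop.centroid[1])),
            area_um2=float(area_um2),
            circularity=float(circ),
            touches_border=bool(touches),
            mean_intensity={"DAPI": float(prop.intensity_mean)},
            integrated_intensity={"DAPI": float(prop.intensity_mean * prop.area)},
        ))
        next_id += 1
    return NucleusLabelMap(new_labels, field_id=label_map.field_id), records


def count_cells(records: list[NucleusRecord]) -> int:
    """Number of nuclei retained in a field (the per-field cell count)."""
    return len(records)


def segment_field(field: ImageField, cfg: PipelineConfig
                  ) -> tuple[NucleusLabelMap, list[NucleusRecord]]:
    """Threshold → label → filter the DAPI channel of a 2-D field."""
    dapi = field.channels[cfg.dapi_channel]
    mask = threshold_fixed(dapi, cfg.dapi_threshold)
    label_map = label_components(mask, cfg.connectivity, field_id=field.field_id)
    return filter_nuclei(label_map, dapi, cfg, field.pixel_size_um)
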