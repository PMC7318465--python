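"""Calibrated multi-channel field I/O, Z-projection, background subtraction.

A *field* is one microscope field of view: an ordered set of named channels
(e.g. ``DAPI``, ``RBM45``, ``SAFB``) sharing a pixel grid, plus the physical
pixel calibration and subject/group metadata.  Fields are stored as plain
multi-page TIFFs; metadata travels in a study manifest (see
:mod:`nucleofoci.pipeline`) or is supplied by the caller.

This module also owns :class:`PipelineConfig`, the single bag of tunables for
the whole analysis, serialisable to/from YAML.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml
from skimage.restoration import rolling_ball

logger = logging.getLogger("nucleofoci")

#: X/Y sampling interval of the acquisition system, in micrometres per pixel.
DEFAULT_PIXEL_SIZE_UM = 0.102


class InputError(ValueError):
    """Raised for malformed user inputs (files, parameters, tables)."""


@dataclass
class ImageField:
    """One calibrated multi-channel field.

    Channels are 2-D ``(rows, cols)`` arrays, or 3-D ``(slices, rows, cols)``
    for Z-stacks prior to projection.  All channels share a shape.
    """

    field_id: str
    subject_id: str
    group_label: str
    channels: dict[str, np.ndarray]
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise InputError("pixel_size_um must be positive")
        if not self.channels:
            raise InputError("field must have at least one channel")
        shapes = {ch: a.shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise InputError(f"channel shapes differ: {shapes}")
        for name, arr in self.channels.items():
            if not np.all(np.isfinite(arr)):
                raise InputError(f"channel {name!r} contains non-finite values")
            if np.any(arr < 0):
                raise InputError(f"channel {name!r} contains negative intensities")

    @property
    def is_stack(self) -> bool:
        return next(iter(self.channels.values())).ndim == 3

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2


@dataclass
class PipelineConfig:
    """All tunables of the analysis, with field-realistic defaults.

    Units: areas in μm² (converted to pixels through the field calibration),
    lengths in pixels where suffixed ``_px``, intensities on the native scale
    of the image.
    """

    # channel roles
    dapi_channel: str = "DAPI"
    inclusion_channel: str = "RBM45"
    reference_channel: str | None = "SAFB"

    # nuclei segmentation
    dapi_threshold: float = 0.25            # fraction of per-image dynamic range
    connectivity: int = 8                   # 4 or 8
    nucleus_area_range_um2: tuple[float, float] = (40.0, 300.0)
    nucleus_circularity_range: tuple[float, float] = (0.3, 1.0)
    exclude_border: bool = True

    # foci detection (RATS)
    rats_p: float = 2.0                     # gradient exponent
    rats_noise_sigma: float = 5.0           # gradient noise scale sigma_g
    rats_lambda: float = 3.0                # noise multiplier
    rats_min_leaf_px: int = 16
    focus_area_range_um2: tuple[float, float] = (0.2, 3.0)

    # intensity / statistics
    zscore_ddof: int = 1
    alpha: float = 0.05

    # preprocessing
    projection_method: str = "max"          # {max, mean}
    background_subtract: bool = False
    background_radius_px: float = 50.0

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 < self.dapi_threshold < 1.0:
            raise InputError("dapi_threshold must lie strictly in (0, 1)")
        if self.connectivity not in (4, 8):
            raise InputError("connectivity must be 4 or 8")
        for name in ("nucleus_area_range_um2", "nucleus_circularity_range",
                     "focus_area_range_um2"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise InputError(f"{name} must be a nonempty interval")
        clo, chi = self.nucleus_circularity_range
        if clo < 0 or chi > 1:
            raise InputError("circularity range must lie within [0, 1]")
        if self.rats_p <= 0:
            raise InputError("rats_p must be positive")
        if self.rats_noise_sigma < 0:
            raise InputError("rats_noise_sigma must be non-negative")
        if self.rats_min_leaf_px < 2:
            raise InputError("rats_min_leaf_px must be at least 2")
        if self.projection_method not in ("max", "mean"):
            raise InputError("projection_method must be 'max' or 'mean'")
        if not 0 < self.alpha < 1:
            raise InputError("alpha must lie in (0, 1)")
        if self.background_radius_px < 1:
            raise InputError("background_radius_px must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        for k, v in raw.items():
            if isinstance(v, list):
                raw[k] = tuple(v)
        return cls(**raw)


def read_field(
    path: str | Path,
    channel_names: list[str],
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    field_id: str | None = None,
    subject_id: str = "",
    group_label: str = "",
) -> ImageField:
    """Read a single- or multi-page TIFF into an :class:`ImageField`.

    Page layout convention: the leading axis enumerates channels in
    ``channel_names`` order; an optional second axis enumerates Z-slices
    (i.e. arrays of shape ``(C, H, W)`` or ``(C, Z, H, W)``).  A flat stack of
    ``C*Z`` pages is reshaped channel-major.
    """
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read TIFF {path}: {exc}") from exc
    n_ch = len(channel_names)
    if arr.ndim == 2:
        if n_ch != 1:
            raise InputError(
                f"{path}: single-page TIFF but {n_ch} channel names given")
        planes = arr[None]
    elif arr.ndim == 3:
        if arr.shape[0] == n_ch:
            planes = arr
        elif arr.shape[0] % n_ch == 0:
            planes = arr.reshape(n_ch, arr.shape[0] // n_ch, *arr.shape[1:])
        else:
            raise InputError(
                f"{path}: {arr.shape[0]} pages not divisible by "
                f"{n_ch} channels")
    elif arr.ndim == 4:
        if arr.shape[0] != n_ch:
            raise InputError(
                f"{path}: leading axis {arr.shape[0]} != {n_ch} channels")
        planes = arr
    else:
        raise InputError(f"{path}: unsupported TIFF dimensionality {arr.ndim}")
    channels = {name: np.asarray(planes[i]) for i, name in enumerate(channel_names)}
    return ImageField(
        field_id=field_id if field_id is not None else path.stem,
        subject_id=subject_id,
        group_label=group_label,
        channels=channels,
        pixel_size_um=pixel_size_um,
    )


def write_field(field: ImageField, path: str | Path) -> None:
    """Write a field as a multi-page TIFF, channels on the leading axis.

    Integer channels are written losslessly; float channels as float32.
    """
    arrs = list(field.channels.values())
    stack = np.stack(arrs, axis=0)
    if not np.issubdtype(stack.dtype, np.integer):
        stack = stack.astype(np.float32)
    tifffile.imwrite(Path(path), stack, photometric="minisblack")


def project_stack(field: ImageField, method: str | None = None) -> ImageField:
    """Collapse a Z-stack field to 2-D by per-pixel ``max`` or ``mean``.

    Already-2-D fields are returned unchanged with a logged notice.
    Maximum projection is the default analysis plane: it preserves punctate
    structures that occupy only a few focal planes.
    """
    method = method or "max"
    if method not in ("max", "mean"):
        raise InputError("projection method must be 'max' or 'mean'")
    if not field.is_stack:
        logger.info("field %s already 2-D; projection skipped", field.field_id)
        return field
    op = np.max if method == "max" else np.mean
    channels = {ch: op(arr, axis=0) for ch, arr in field.channels.items()}
    return dataclasses.replace(field, channels=channels)


def subtract_background(image: np.ndarray, radius_px: float = 50.0) -> np.ndarray:
    """Rolling-ball background subtraction, clipped at zero.

    Estimates the background as the surface traced by a ball of the given
    radius rolled under the intensity landscape and subtracts it, so the
    output is pixelwise <= the input and >= 0.  Structures smaller than the
    ball (nuclei, foci) are preserved.
    """
    image = np.asarray(image, dtype=float)
    if radius_px < 1:
        raise InputError("radius_px must be >= 1")
    if not np.all(np.isfinite(image)):
        raise InputError("image contains non-finite pixels")
    background = rolling_ball(image, radius=radius_px)
    return np.clip(image - background, 0.0, None)
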