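"""Synthetic fluorescence microscopy fields with exact ground truth.

The generator emulates the tissue-imaging conditions the analysis was built
for: fields of a few dozen non-overlapping roughly-elliptical nuclei (DAPI
channel), an inclusion channel with a dim diffuse nucleoplasmic level plus
bright sub-micron Gaussian puncta whose per-nucleus count follows a
zero-inflated Poisson capped at 17 (the observed per-cell range), and a
reference (SAFB-like) channel whose nuclear level decreases linearly with
the focus count — the coupling the regression analysis is meant to recover.
All channels are Gaussian-blurred and carry additive read noise.

Every random draw flows from one seed, so a (spec, seed) pair regenerates
bit-identical images and truth tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .image_io import ImageField, InputError, write_field

logger = logging.getLogger("nucleofoci")

FOCUS_COUNT_CAP = 17
FIELDS_PER_SUBJECT = 8


@dataclass
class SyntheticSpec:
    """Study conditions for one group of synthetic fields.

    Defaults target a control-like dentate field: ~50 nuclei per field and a
    mean of ~0.44 inclusions per cell.  Intensities are arbitrary units on a
    uint16-like scale; lengths are μm unless suffixed ``_px``.
    """

    image_shape: tuple[int, int] = (768, 768)
    pixel_size_um: float = 0.2

    # nuclei
    n_nuclei: int = 50
    n_nuclei_sd: float = 3.0                 # per-field count spread
    nucleus_radius_um: tuple[float, float] = (4.0, 6.0)
    min_separation_um: float = 2.0           # edge-to-edge
    ellipse_ratio_max: float = 1.1           # max axis ratio (area-preserving)
    dapi_mean: float = 180.0
    dapi_sd: float = 15.0                    # per-nucleus brightness spread
    background_level: float = 5.0

    # inclusion channel
    inclusion_diffuse: float = 10.0          # diffuse nucleoplasmic level
    focus_rate: float = 1.76                 # Poisson rate of the count mixture
    zero_inflation: float = 0.75             # extra mass at zero
    focus_cap: int = FOCUS_COUNT_CAP
    focus_diameter_um: tuple[float, float] = (0.8, 1.5)   # FWHM range
    focus_amplitude: float = 150.0
    # centre-to-centre; large enough that distinct foci stay optically
    # resolvable after blur, keeping the truth consistent with the render
    focus_min_separation_um: float = 2.5
    focus_margin_um: float = 1.0             # keep-out from the nuclear rim

    # reference (SAFB-like) channel: level = baseline - decrement * count
    safb_baseline: float = 120.0
    safb_decrement: float = 10.0
    safb_noise_sd: float = 8.0               # per-nucleus level spread

    # optics / detector
    blur_sigma_px: float = 1.0
    read_noise_sd: float = 4.0
    shot_noise: bool = False

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise InputError("pixel_size_um must be positive")
        if self.n_nuclei < 0:
            raise InputError("n_nuclei must be non-negative")
        for name in ("nucleus_radius_um", "focus_diameter_um"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise InputError(f"{name} must be a positive interval")
        if self.focus_diameter_um[1] >= 2 * self.nucleus_radius_um[0]:
            raise InputError("foci must fit inside the smallest nucleus")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise InputError("zero_inflation must lie in [0, 1]")
        if self.focus_rate < 0:
            raise InputError("focus_rate must be non-negative")
        if self.focus_cap != FOCUS_COUNT_CAP:
            raise InputError(f"focus_cap is fixed at {FOCUS_COUNT_CAP}")
        if self.safb_decrement < 0:
            raise InputError("safb_decrement must be non-negative")
        for name in ("dapi_sd", "safb_noise_sd", "read_noise_sd",
                     "blur_sigma_px", "n_nuclei_sd"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")

    @property
    def mean_inclusions_per_cell(self) -> float:
        """Expected per-nucleus count, ignoring the (negligible) cap."""
        return (1.0 - self.zero_inflation) * self.focus_rate


#: (zero_inflation, focus_rate) pairs whose means track the published
#: per-cell dentate inclusion burdens: 0.44, 0.98, 1.49, 2.38.
GROUP_PRESETS: dict[str, tuple[float, float]] = {
    "control": (0.75, 1.76),
    "AD": (0.60, 2.45),
    "ALS": (0.50, 2.98),
    "FTLD": (0.30, 3.40),
}


def group_spec(name: str, **overrides) -> SyntheticSpec:
    """A :class:`SyntheticSpec` preset for one study group."""
    if name not in GROUP_PRESETS:
        raise InputError(f"unknown group preset {name!r}")
    pi0, rate = GROUP_PRESETS[name]
    return SyntheticSpec(zero_inflation=pi0, focus_rate=rate, **overrides)


@dataclass
class GroundTruth:
    """Generator-side truth for one field."""

    field_id: str
    cell_count: int
    nuclei: pd.DataFrame  # nucleus_index, center_r, center_c, radius_um,
    #                       focus_count, dapi_level, safb_level

    @property
    def total_foci(self) -> int:
        if len(self.nuclei) == 0:
            return 0
        return int(self.nuclei["focus_count"].sum())


def sample_focus_counts(spec: SyntheticSpec, n: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw n per-nucleus counts from the capped zero-inflated Poisson."""
    zeros = rng.random(n) < spec.zero_inflation
    counts = rng.poisson(spec.focus_rate, size=n)
    counts[zeros] = 0
    return np.minimum(counts, spec.focus_cap)


def _place_nuclei(spec: SyntheticSpec, n: int, rng: np.random.Generator,
                  max_tries: int = 20000):
    """Rejection-sample non-overlapping nucleus centres and radii (px)."""
    h, w = spec.image_shape
    px = spec.pixel_size_um
    r_lo, r_hi = (r / px for r in spec.nucleus_radius_um)
    sep = spec.min_separation_um / px
    margin_extra = 3.0 * spec.blur_sigma_px + 2.0
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    tries = 0
    while len(centers) < n:
        if tries >= max_tries:
            raise InputError(
                f"could not place {n} nuclei in a {h}x{w} field "
                "(field too crowded); enlarge the field or shrink nuclei")
        tries += 1
        r = rng.uniform(r_lo, r_hi)
        margin = r * spec.ellipse_ratio_max + margin_extra
        cr = rng.uniform(margin, h - margin)
        cc = rng.uniform(margin, w - margin)
        ok = all((cr - pr) ** 2 + (cc - pc) ** 2 >= (r + prr + sep) ** 2
                 for (pr, pc), prr in zip(centers, radii))
        if ok:
            centers.append((cr, cc))
            radii.append(r)
    return centers, radii


def _place_foci(center, inner_radius_px: float, k: int, sep_px: float,
                rng: np.random.Generator, max_tries: int = 400):
    """Place up to k focus centres inside a disc with minimum separation."""
    placed: list[tuple[float, float]] = []
    tries = 0
    while len(placed) < k and tries < max_tries:
        tries += 1
        rho = inner_radius_px * math.sqrt(rng.random())
        theta = rng.uniform(0, 2 * math.pi)
        fr = center[0] + rho * math.cos(theta)
        fc = center[1] + rho * math.sin(theta)
        if all((fr - pr) ** 2 + (fc - pc) ** 2 >= sep_px**2
               for pr, pc in placed):
            placed.append((fr, fc))
    return placed


def _ellipse_mask(shape, center, a: float, b: float, theta: float):
    """Boolean mask of a rotated filled ellipse, plus its bounding box."""
    cr, cc = center
    rmax = max(a, b)
    r0 = max(0, int(math.floor(cr - rmax - 1)))
    r1 = min(shape[0], int(math.ceil(cr + rmax + 2)))
    c0 = max(0, int(math.floor(cc - rmax - 1)))
    c1 = min(shape[1], int(math.ceil(cc + rmax + 2)))
    rr, cc_ = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    dr, dc = rr - cr, cc_ - cc
    u = dr * math.cos(theta) + dc * math.sin(theta)
    v = -dr * math.sin(theta) + dc * math.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0, (r0, r1, c0, c1)


def generate_field(
    spec: SyntheticSpec,
    seed: int,
    field_id: str = "synthetic",
    subject_id: str = "S1",
    group_label: str = "synthetic",
    n_nuclei: int | None = None,
    render: bool = True,
) -> tuple[ImageField | None, GroundTruth]:
    """Render one synthetic field and its ground truth.

    With ``render=False`` only the truth table is produced (counts, SAFB
    levels, geometry) — used for distribution-level studies where the images
    themselves are not needed.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    h, w = spec.image_shape
    px = spec.pixel_size_um
    n = spec.n_nuclei if n_nuclei is None else n_nuclei

    if render:
        centers, radii = _place_nuclei(spec, n, rng)
    else:
        centers = [(math.nan, math.nan)] * n
        radii = list(rng.uniform(*(r / px for r in spec.nucleus_radius_um),
                                 size=n)) if n else []

    counts = sample_focus_counts(spec, n, rng)
    dapi_levels = rng.normal(spec.dapi_mean, spec.dapi_sd, size=n)
    safb_levels = np.maximum(
        0.0,
        spec.safb_baseline - spec.safb_decrement * counts
        + rng.normal(0.0, spec.safb_noise_sd, size=n))

    image_field = None
    placed_counts = np.asarray(counts, dtype=int).copy()
    if render:
        dapi = np.full((h, w), spec.background_level, dtype=float)
        incl = np.zeros((h, w), dtype=float)
        safb = np.zeros((h, w), dtype=float)
        sep_f = spec.focus_min_separation_um / px
        margin_f = spec.focus_margin_um / px
        d_lo, d_hi = spec.focus_diameter_um
        fwhm_to_sigma = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        for i, ((cr, cc), r) in enumerate(zip(centers, radii)):
            s = rng.uniform(1.0, spec.ellipse_ratio_max)
            theta = rng.uniform(0, math.pi)
            a, b = r * s, r / s
            mask, (r0, r1, c0, c1) = _ellipse_mask((h, w), (cr, cc), a, b, theta)
            dapi[r0:r1, c0:c1][mask] = dapi_levels[i]
            incl[r0:r1, c0:c1][mask] += spec.inclusion_diffuse
            safb[r0:r1, c0:c1][mask] = safb_levels[i]
            inner = b - margin_f
            foci = _place_foci((cr, cc), max(inner, 0.0), int(counts[i]),
                               sep_f, rng)
            if len(foci) < counts[i]:
                logger.debug("field %s nucleus %d: placed %d of %d foci",
                             field_id, i, len(foci), counts[i])
                placed_counts[i] = len(foci)
            for fr, fc in foci:
                sigma = rng.uniform(d_lo, d_hi) / px * fwhm_to_sigma
                ext = int(math.ceil(4 * sigma)) + 1
                fr0, fr1 = max(0, int(fr) - ext), min(h, int(fr) + ext + 1)
                fc0, fc1 = max(0, int(fc) - ext), min(w, int(fc) + ext + 1)
                rr, cc_ = np.meshgrid(np.arange(fr0, fr1), np.arange(fc0, fc1),
                                      indexing="ij")
                incl[fr0:fr1, fc0:fc1] += spec.focus_amplitude * np.exp(
                    -((rr - fr) ** 2 + (cc_ - fc) ** 2) / (2.0 * sigma**2))
        channels = {}
        for name, img in (("DAPI", dapi), ("RBM45", incl), ("SAFB", safb)):
            if spec.blur_sigma_px > 0:
                img = gaussian_filter(img, spec.blur_sigma_px)
            if spec.shot_noise:
                img = rng.poisson(np.clip(img, 0, None)).astype(float)
            if spec.read_noise_sd > 0:
                img = img + rng.normal(0.0, spec.read_noise_sd, size=img.shape)
            channels[name] = np.clip(img, 0.0, None)
        image_field = ImageField(
            field_id=field_id, subject_id=subject_id, group_label=group_label,
            channels=channels, pixel_size_um=px)

    nuclei = pd.DataFrame({
        "nucleus_index": np.arange(n, dtype=int),
        "center_r": [c[0] for c in centers],
        "center_c": [c[1] for c in centers],
        "radius_um": np.asarray(radii, dtype=float) * px,
        "focus_count": placed_counts,
        "dapi_level": dapi_levels,
        "safb_level": safb_levels,
    })
    truth = GroundTruth(field_id=field_id, cell_count=n, nuclei=nuclei)
    return image_field, truth


@dataclass
class StudyBundle:
    """A generated multi-group study: fields, truth and regeneration recipe."""

    fields: list  # (ImageField | None, GroundTruth) pairs
    manifest: dict
    truth_table: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        rows = []
        for img, truth in self.fields:
            meta = self.manifest["fields"][truth.field_id]
            t = truth.nuclei.copy()
            t.insert(0, "field_id", truth.field_id)
            t.insert(1, "subject_id", meta["subject_id"])
            t.insert(2, "group_label", meta["group_label"])
            rows.append(t)
        self.truth_table = (pd.concat(rows, ignore_index=True) if rows
                            else pd.DataFrame())

    def save(self, out_dir: str | Path) -> Path:
        """Write TIFFs, truth CSVs and a regeneration manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for img, truth in self.fields:
            if img is None:
                raise InputError("cannot save a study generated with render=False")
            write_field(img, out / f"{truth.field_id}.tif")
        self.truth_table.to_csv(out / "truth_nuclei.csv", index=False,
                                float_format="%.6g")
        per_field = pd.DataFrame([
            {"field_id": t.field_id,
             "subject_id": self.manifest["fields"][t.field_id]["subject_id"],
             "group_label": self.manifest["fields"][t.field_id]["group_label"],
             "cell_count": t.cell_count,
             "total_foci": t.total_foci}
            for _, t in self.fields])
        per_field.to_csv(out / "truth_fields.csv", index=False)
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=1, sort_keys=True))
        return out


def generate_study(
    spec_per_group: dict[str, SyntheticSpec],
    n_subjects: dict[str, int],
    seed: int,
    fields_per_subject: int = FIELDS_PER_SUBJECT,
    subject_jitter_sd: float = 0.1,
    render: bool = True,
) -> StudyBundle:
    """Generate ``n_subjects[g] x fields_per_subject`` fields per group.

    Each subject's mean inclusion rate is jittered by a lognormal factor
    (sd ``subject_jitter_sd`` on the log scale, default ~10%) to emulate
    between-subject heterogeneity; each field's nucleus count is drawn around
    the spec target.
    """
    if set(spec_per_group) != set(n_subjects):
        raise InputError("spec_per_group and n_subjects must share keys")
    master = np.random.default_rng(seed)
    fields = []
    manifest_fields: dict[str, dict] = {}
    for group in spec_per_group:
        spec = spec_per_group[group]
        for s in range(n_subjects[group]):
            subject_id = f"{group}_subj{s + 1:02d}"
            jitter = math.exp(master.normal(0.0, subject_jitter_sd))
            subj_spec = dataclasses.replace(
                spec, focus_rate=spec.focus_rate * jitter)
            for f in range(fields_per_subject):
                field_id = f"{subject_id}_f{f + 1:02d}"
                field_seed = int(master.integers(2**31))
                n = max(0, int(round(master.normal(spec.n_nuclei,
                                                   spec.n_nuclei_sd))))
                img, truth = generate_field(
                    subj_spec, field_seed, field_id=field_id,
                    subject_id=subject_id, group_label=group,
                    n_nuclei=n, render=render)
                fields.append((img, truth))
                manifest_fields[field_id] = {
                    "file": f"{field_id}.tif",
                    "subject_id": subject_id,
                    "group_label": group,
                    "channels": ["DAPI", "RBM45", "SAFB"],
                    "pixel_size_um": spec.pixel_size_um,
                    "seed": field_seed,
                }
    manifest = {
        "generator": "nucleofoci.synthetic",
        "seed": seed,
        "fields_per_subject": fields_per_subject,
        "subject_jitter_sd": subject_jitter_sd,
        "groups": {g: dataclasses.asdict(spec_per_group[g])
                   for g in spec_per_group},
        "n_subjects": dict(n_subjects),
        "fields": manifest_fields,
    }
    return StudyBundle(fields=fields, manifest=manifest)


def agreement(automated: pd.DataFrame, truth: pd.DataFrame) -> float:
    """Fraction of fields where automated and true counts both match exactly.

    Both tables need ``field_id``, ``cell_count`` and ``total_foci`` columns;
    a field agrees only when the automated cell count *and* the total focus
    count equal the generator truth.
    """
    required = {"field_id", "cell_count", "total_foci"}
    for name, df in (("automated", automated), ("truth", truth)):
        missing = required - set(df.columns)
        if missing:
            raise InputError(f"{name} table missing columns {sorted(missing)}")
    if set(automated["field_id"]) != set(truth["field_id"]):
        raise InputError("automated and truth tables cover different fields")
    merged = automated.merge(truth, on="field_id", suffixes=("_auto", "_true"))
    ok = ((merged["cell_count_auto"] == merged["cell_count_true"])
          & (merged["total_foci_auto"] == merged["total_foci_true"]))
    return float(ok.mean())
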