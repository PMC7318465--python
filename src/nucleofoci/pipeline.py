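"""End-to-end orchestration: read → project → (background) → segment →
filter → foci → intensity → summarise → statistics, plus the validation
harness that checks automated counts against synthetic ground truth.

All tabular outputs are written with fixed row ordering and fixed float
formatting so identical inputs and configuration produce byte-identical
files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as gstats
from .foci import FocusRecord, detect_foci, foci_per_nucleus
from .image_io import ImageField, InputError, PipelineConfig, read_field, \
    project_stack, subtract_background
from .intensity import nuclear_intensity, zscore_table
from .segmentation import NucleusRecord, count_cells, segment_field
from .synthetic import SyntheticSpec, agreement, generate_field

logger = logging.getLogger("nucleofoci")

FLOAT_FORMAT = "%.6g"


@dataclass
class FieldResult:
    """All per-field outputs of the quantification stages."""

    field_id: str
    subject_id: str
    group_label: str
    cell_count: int
    nuclei: list[NucleusRecord]
    foci: list[FocusRecord]
    nucleus_table: pd.DataFrame
    focus_table: pd.DataFrame
    intensity_table: pd.DataFrame


def _nucleus_table(result_meta: dict, nuclei: list[NucleusRecord]) -> pd.DataFrame:
    rows = []
    for n in nuclei:
        rows.append({**result_meta,
                     "nucleus_id": n.nucleus_id,
                     "centroid_row": n.centroid_rc[0],
                     "centroid_col": n.centroid_rc[1],
                     "area_um2": n.area_um2,
                     "circularity": n.circularity,
                     "touches_border": n.touches_border,
                     "focus_count": n.focus_count})
    cols = [*result_meta, "nucleus_id", "centroid_row", "centroid_col",
            "area_um2", "circularity", "touches_border", "focus_count"]
    return pd.DataFrame(rows, columns=cols)


def _focus_table(result_meta: dict, foci: list[FocusRecord]) -> pd.DataFrame:
    rows = [{**result_meta,
             "focus_id": f.focus_id,
             "nucleus_id": f.nucleus_id,
             "centroid_row": f.centroid_rc[0],
             "centroid_col": f.centroid_rc[1],
             "area_um2": f.area_um2,
             "mean_intensity": f.mean_intensity} for f in foci]
    cols = [*result_meta, "focus_id", "nucleus_id", "centroid_row",
            "centroid_col", "area_um2", "mean_intensity"]
    return pd.DataFrame(rows, columns=cols)


def process_field(field: ImageField, cfg: PipelineConfig) -> FieldResult:
    """Run the single-field stages in order and assemble the result tables."""
    if field.is_stack:
        field = project_stack(field, cfg.projection_method)
    if cfg.background_subtract:
        channels = {ch: subtract_background(img, cfg.background_radius_px)
                    for ch, img in field.channels.items()}
        field = dataclasses.replace(field, channels=channels)
    label_map, nuclei = segment_field(field, cfg)
    foci = detect_foci(field.channels[cfg.inclusion_channel], label_map, cfg,
                       field.pixel_size_um)
    nuclei = foci_per_nucleus(foci, nuclei)
    intensity = nuclear_intensity(field, label_map)
    for n in nuclei:  # carry all channel measurements on the records too
        sub = intensity[intensity["nucleus_id"] == n.nucleus_id]
        n.mean_intensity = dict(zip(sub["channel"], sub["mean_intensity"]))
        n.integrated_intensity = dict(zip(sub["channel"],
                                          sub["integrated_intensity"]))
    meta = {"field_id": field.field_id, "subject_id": field.subject_id,
            "group_label": field.group_label}
    logger.info("field %s: %d cells, %d foci", field.field_id,
                count_cells(nuclei), len(foci))
    return FieldResult(
        field_id=field.field_id, subject_id=field.subject_id,
        group_label=field.group_label, cell_count=count_cells(nuclei),
        nuclei=nuclei, foci=foci,
        nucleus_table=_nucleus_table(meta, nuclei),
        focus_table=_focus_table(meta, foci),
        intensity_table=intensity.assign(
            subject_id=field.subject_id, group_label=field.group_label))


def _load_manifest(input_dir: Path) -> dict:
    manifest_path = input_dir / "manifest.json"
    if not manifest_path.exists():
        raise InputError(f"no manifest.json in {input_dir}")
    manifest = json.loads(manifest_path.read_text())
    if not manifest.get("fields"):
        raise InputError(f"manifest in {input_dir} lists no fields")
    return manifest


def study_statistics(nucleus_table: pd.DataFrame,
                     intensity_table: pd.DataFrame | None,
                     cfg: PipelineConfig) -> dict:
    """The between-group battery over a per-nucleus results table.

    Pairwise Mann-Whitney (Bonferroni-adjusted) on per-cell inclusion counts;
    OLS of reference-channel nuclear intensity on inclusion count; and, when
    an external per-cell ``cytoplasmic_count`` column is present, the pooled
    two-proportion test of nuclear vs cytoplasmic inclusion-bearing cells.
    """
    out: dict = {"comparisons": [], "regression": None, "proportions": None,
                 "alpha": cfg.alpha}
    groups = sorted(nucleus_table["group_label"].unique())
    if len(groups) >= 2:
        samples = {g: nucleus_table.loc[nucleus_table["group_label"] == g,
                                        "focus_count"].to_numpy(float)
                   for g in groups}
        for r in gstats.pairwise_mann_whitney(samples):
            out["comparisons"].append(dataclasses.asdict(r))
    if (cfg.reference_channel is not None and intensity_table is not None
            and len(intensity_table)):
        ref = intensity_table[
            intensity_table["channel"] == cfg.reference_channel]
        merged = nucleus_table.merge(
            ref[["field_id", "nucleus_id", "mean_intensity"]],
            on=["field_id", "nucleus_id"], how="inner")
        if len(merged) >= 3 and merged["focus_count"].nunique() > 1:
            reg = gstats.linear_regression(merged["focus_count"],
                                           merged["mean_intensity"])
            out["regression"] = {
                "response": f"{cfg.reference_channel} mean nuclear intensity",
                "predictor": "nuclear inclusion count",
                **dataclasses.asdict(reg)}
    if "cytoplasmic_count" in nucleus_table.columns:
        n = len(nucleus_table)
        k_nuc = int((nucleus_table["focus_count"] >= 1).sum())
        k_cyt = int((nucleus_table["cytoplasmic_count"] >= 1).sum())
        r = gstats.two_proportion_test(k_nuc, n, k_cyt, n)
        r.comparison = "cells with >=1 nuclear vs >=1 cytoplasmic inclusion"
        out["proportions"] = dataclasses.asdict(r)
    return out


def run_pipeline(
    cfg: PipelineConfig,
    input_dir: str | Path,
    out_dir: str | Path | None = None,
) -> tuple[list[FieldResult], dict[str, gstats.GroupSummary], dict]:
    """Quantify a study directory (TIFF fields + ``manifest.json``).

    Per-field failures are logged and the field is skipped (recorded in the
    run report); an empty or unreadable study is an input error.  When
    ``out_dir`` is given all result tables are written there.
    """
    input_dir = Path(input_dir)
    if not input_dir.is_dir():
        raise InputError(f"{input_dir} is not a directory")
    manifest = _load_manifest(input_dir)
    cyto = None
    cyto_path = input_dir / "cytoplasmic_counts.csv"
    if cyto_path.exists():  # externally supplied manual counts
        cyto = pd.read_csv(cyto_path)

    results: list[FieldResult] = []
    failures: dict[str, str] = {}
    for field_id in sorted(manifest["fields"]):
        meta = manifest["fields"][field_id]
        try:
            fld = read_field(
                input_dir / meta["file"], meta["channels"],
                pixel_size_um=meta.get("pixel_size_um", None) or 0.102,
                field_id=field_id, subject_id=meta.get("subject_id", ""),
                group_label=meta.get("group_label", ""))
            results.append(process_field(fld, cfg))
        except Exception as exc:  # noqa: BLE001 - isolate per-field failures
            logger.error("field %s failed: %s", field_id, exc)
            failures[field_id] = str(exc)
    if not results:
        raise InputError("no field in the study could be processed")

    nucleus_table = pd.concat([r.nucleus_table for r in results],
                              ignore_index=True)
    if cyto is not None and {"field_id", "nucleus_id",
                             "cytoplasmic_count"} <= set(cyto.columns):
        nucleus_table = nucleus_table.merge(
            cyto[["field_id", "nucleus_id", "cytoplasmic_count"]],
            on=["field_id", "nucleus_id"], how="left")
        nucleus_table["cytoplasmic_count"] = \
            nucleus_table["cytoplasmic_count"].fillna(0)
    nonempty_foci = [r.focus_table for r in results if len(r.focus_table)]
    focus_table = (pd.concat(nonempty_foci, ignore_index=True)
                   if nonempty_foci else results[0].focus_table)
    intensity_table = pd.concat([r.intensity_table for r in results],
                                ignore_index=True)
    ztable = (zscore_table(intensity_table, ddof=cfg.zscore_ddof)
              if len(intensity_table) >= 2 else intensity_table)

    fields_df = pd.DataFrame([
        {"field_id": r.field_id, "subject_id": r.subject_id,
         "group_label": r.group_label, "cell_count": r.cell_count,
         "total_foci": len(r.foci)} for r in results])
    summaries = {}
    for group, fsub in fields_df.groupby("group_label"):
        nsub = nucleus_table[nucleus_table["group_label"] == group]
        summaries[group] = gstats.summarize_group(fsub, nsub, group)
    stats_out = study_statistics(nucleus_table, intensity_table, cfg)
    stats_out["failed_fields"] = failures

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        order = ["group_label", "subject_id", "field_id", "nucleus_id"]
        write_csv(nucleus_table.sort_values(order), out / "nuclei.csv")
        write_csv(focus_table.sort_values(order[:3] + ["focus_id"]),
                  out / "foci.csv")
        write_csv(intensity_table.sort_values(order + ["channel"]),
                  out / "intensity.csv")
        if "z" in getattr(ztable, "columns", []):
            write_csv(ztable.sort_values(order + ["channel"]),
                      out / "zscores.csv")
        write_csv(fields_df.sort_values(order[:3]), out / "fields.csv")
        summary_df = pd.DataFrame(
            [dataclasses.asdict(s) for s in summaries.values()]).drop(
                columns=["sem_units"]).sort_values("group_label")
        write_csv(summary_df, out / "group_summary.csv")
        (out / "stats.json").write_text(
            json.dumps(stats_out, indent=1, sort_keys=True, default=float))
    return results, summaries, stats_out


def write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


@dataclass
class ValidationReport:
    """Automated-vs-truth agreement over generated validation fields."""

    n_fields: int
    agreement_fraction: float
    passed: bool
    threshold: float
    per_field: pd.DataFrame


#: the validation criterion: automated counts must agree with reference
#: counts on at least this fraction of fields
AGREEMENT_THRESHOLD = 0.95


def validate_run(
    cfg: PipelineConfig,
    spec: SyntheticSpec,
    n_fields: int = 20,
    seed: int = 0,
    threshold: float = AGREEMENT_THRESHOLD,
) -> ValidationReport:
    """Generate ``n_fields`` synthetic fields, quantify, score agreement.

    A field agrees when the automated cell count and the total nuclear focus
    count both exactly match the generator's truth; the report passes when
    the agreeing fraction is >= ``threshold``.  Falling short is a reported
    failure, not an error.
    """
    if n_fields < 10:
        raise InputError("validation requires at least 10 fields")
    master = np.random.default_rng(seed)
    auto_rows, truth_rows = [], []
    for i in range(n_fields):
        fid = f"val{i + 1:03d}"
        img, truth = generate_field(spec, int(master.integers(2**31)),
                                    field_id=fid)
        result = process_field(img, cfg)
        auto_rows.append({"field_id": fid, "cell_count": result.cell_count,
                          "total_foci": len(result.foci)})
        truth_rows.append({"field_id": fid, "cell_count": truth.cell_count,
                           "total_foci": truth.total_foci})
    auto = pd.DataFrame(auto_rows)
    tru = pd.DataFrame(truth_rows)
    frac = agreement(auto, tru)
    per_field = auto.merge(tru, on="field_id", suffixes=("_auto", "_true"))
    report = ValidationReport(n_fields=n_fields, agreement_fraction=frac,
                              passed=frac >= threshold, threshold=threshold,
                              per_field=per_field)
    logger.info("validation: %.1f%% agreement over %d fields (%s)",
                100 * frac, n_fields, "pass" if report.passed else "fail")
    return report
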