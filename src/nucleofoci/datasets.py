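"""Published summary statistics from the post-mortem tissue study of RBM45
inclusion pathology that this pipeline models.

These are group-level aggregates (subjects, total cells counted, mean/SEM
cells per field, mean/SEM nuclear and cytoplasmic RBM45 inclusions per cell)
for hippocampal dentate gyrus granule cells, lumbar spinal cord glial cells
and spinal cord motor neurons; 8 fields were imaged per subject and region.
They serve as worked-example inputs for the aggregation arithmetic and as
anchors for the synthetic generator's group presets — no raw images
underlying them are publicly deposited.
"""

from __future__ import annotations

import pandas as pd

FIELDS_PER_SUBJECT = 8

_ROWS = [
    # region, group, n_subjects, total_cells, mean_cells_field, sem_cells_field,
    # mean_nuc_incl_cell, sem_nuc_incl_cell, mean_cyt_incl_cell, sem_cyt_incl_cell
    ("dentate_gyrus", "control", 10, 4145, 51.81, 4.92, 0.44, 0.09, 0.0, 0.0),
    ("dentate_gyrus", "AD", 5, 1590, 39.75, 8.32, 0.98, 0.34, 0.044, 0.051),
    ("dentate_gyrus", "ALS", 8, 2943, 45.98, 5.98, 1.49, 0.27, 0.048, 0.055),
    ("dentate_gyrus", "FTLD", 6, 1962, 40.92, 5.81, 2.38, 0.23, 0.109, 0.072),
    ("spinal_glia", "control", 9, 693, 9.62, 1.18, 0.23, 0.06, 0.0, 0.0),
    ("spinal_glia", "ALS", 15, 2689, 22.35, 1.74, 1.04, 0.18, 0.11, 0.47),
    ("spinal_motor_neurons", "control", 9, 308, 4.29, 0.53, 0.0, 0.0, 0.0, 0.0),
    ("spinal_motor_neurons", "ALS", 15, 351, 2.91, 0.42, 0.0, 0.0, 0.15, 0.14),
]

_COLUMNS = [
    "region", "group", "n_subjects", "total_cells",
    "mean_cells_per_field", "sem_cells_per_field",
    "mean_nuclear_inclusions_per_cell", "sem_nuclear_inclusions_per_cell",
    "mean_cytoplasmic_inclusions_per_cell", "sem_cytoplasmic_inclusions_per_cell",
]


def tissue_summary() -> pd.DataFrame:
    """The published per-group summary table as a DataFrame."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)


def dentate_summary() -> pd.DataFrame:
    """Dentate gyrus granule cell rows only (the four-group comparison)."""
    df = tissue_summary()
    return df[df["region"] == "dentate_gyrus"].reset_index(drop=True)
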