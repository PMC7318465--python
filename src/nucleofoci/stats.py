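"""Group statistics: Mann-Whitney U (exact and asymptotic), Bonferroni,
one-way ANOVA with Tukey HSD, OLS regression, two-proportion tests, and the
per-group summary aggregation (cells/field, inclusions/cell with SEMs).

Per-nucleus inclusion counts are strongly right-skewed with a large mass at
zero, so the primary between-group comparison is the nonparametric
Mann-Whitney U test over all group pairs with Bonferroni correction; the
inclusion-count → reference-intensity relationship is assessed by ordinary
least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .image_io import InputError

#: largest pooled sample size for which the exact permutation p is computed
EXACT_LIMIT = 12

#: fields imaged per subject and region in the tissue study design
FIELDS_PER_SUBJECT = 8


@dataclass
class StatsResult:
    test_name: str
    comparison: str
    statistic: float
    p_raw: float
    p_adjusted: float | None = None
    adjustment_method: str | None = None
    n_per_group: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.p_adjusted is not None and self.p_adjusted < self.p_raw - 1e-12:
            raise ValueError("adjusted p below raw p")


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    n: int


@dataclass
class GroupSummary:
    """Per-group aggregate in the summary-table schema of the tissue study."""

    group_label: str
    n_subjects: int
    total_cells: int
    mean_cells_per_field: float
    sem_cells_per_field: float
    mean_nuclear_inclusions_per_cell: float
    sem_nuclear_inclusions_per_cell: float
    mean_cytoplasmic_inclusions_per_cell: float | None = None
    sem_cytoplasmic_inclusions_per_cell: float | None = None
    n_fields: int = 0
    sem_units: dict = field(default_factory=lambda: {
        "cells_per_field": "fields", "inclusions_per_cell": "cells"})


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of the first sample from midrank sums (ties share midranks)."""
    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    return float(r1 - n1 * (n1 + 1) / 2.0)


def mann_whitney(x, y, mode: str = "auto") -> StatsResult:
    """Two-sided Mann-Whitney U test.

    ``mode='exact'`` enumerates every assignment of the pooled values to the
    two groups (handles ties exactly); feasible for n1+n2 <= 12 and selected
    automatically there.  Otherwise the normal approximation with
    tie-corrected variance and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("Mann-Whitney requires two nonempty samples")
    if mode not in ("auto", "exact", "normal"):
        raise InputError("mode must be 'auto', 'exact' or 'normal'")
    n1, n2 = len(x), len(y)
    if mode == "auto":
        mode = "exact" if n1 + n2 <= EXACT_LIMIT else "normal"

    u_obs = _u_statistic(x, y)
    if mode == "exact":
        pooled = np.concatenate([x, y])
        mu = n1 * n2 / 2.0
        dev_obs = abs(u_obs - mu)
        hits = total = 0
        idx_all = frozenset(range(n1 + n2))
        for subset in combinations(range(n1 + n2), n1):
            rest = list(idx_all - set(subset))
            u = _u_statistic(pooled[list(subset)], pooled[rest])
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        p = hits / total
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        p = float(res.pvalue)
    return StatsResult(
        test_name=f"mann-whitney-u ({mode})", comparison="x vs y",
        statistic=u_obs, p_raw=min(1.0, p), n_per_group=(n1, n2))


def bonferroni(p_values) -> list[float]:
    """Bonferroni adjustment: p_i' = min(1, m * p_i), m = family size."""
    ps = list(p_values)
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise InputError(f"p value {p} outside [0, 1]")
    m = len(ps)
    return [min(1.0, m * p) for p in ps]


def pairwise_mann_whitney(samples: dict[str, np.ndarray],
                          mode: str = "auto") -> list[StatsResult]:
    """All pairwise Mann-Whitney comparisons with Bonferroni adjustment.

    The correction family is exactly the set of comparisons run (all pairs).
    """
    names = list(samples)
    results = []
    for a, b in combinations(names, 2):
        r = mann_whitney(samples[a], samples[b], mode=mode)
        r.comparison = f"{a} vs {b}"
        results.append(r)
    adjusted = bonferroni([r.p_raw for r in results])
    for r, p_adj in zip(results, adjusted):
        r.p_adjusted = p_adj
        r.adjustment_method = "bonferroni"
    return results


# ---------------------------------------------------------------------------
# ANOVA + Tukey HSD


def anova_tukey(groups: list, alpha: float = 0.05) -> list[StatsResult]:
    """One-way ANOVA omnibus F followed by all-pairs Tukey HSD.

    Returns the omnibus result first, then one result per pair with the
    studentized-range (family-adjusted) p value.  Groups are labelled by
    position ``g1..gk``.
    """
    if len(groups) < 2:
        raise InputError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size < 2:
            raise InputError("each group needs at least two observations")
    means = [g.mean() for g in arrays]
    if np.ptp(means) == 0.0:
        f_stat, p_omni = 0.0, 1.0
    else:
        f_stat, p_omni = sps.f_oneway(*arrays)
    results = [StatsResult(
        test_name="one-way-anova", comparison="omnibus",
        statistic=float(f_stat), p_raw=float(p_omni),
        n_per_group=tuple(len(g) for g in arrays))]

    data = np.concatenate(arrays)
    labels = np.concatenate([[f"g{i + 1}"] * len(g)
                             for i, g in enumerate(arrays)])
    if np.ptp(data) == 0.0:  # all observations identical: every pair p = 1
        for i, j in combinations(range(len(arrays)), 2):
            results.append(StatsResult(
                test_name="tukey-hsd", comparison=f"g{i + 1} vs g{j + 1}",
                statistic=0.0, p_raw=1.0, p_adjusted=1.0,
                adjustment_method="studentized-range",
                n_per_group=(len(arrays[i]), len(arrays[j]))))
        return results
    tukey = pairwise_tukeyhsd(data, labels, alpha=alpha)
    pairs = list(combinations(tukey.groupsunique, 2))
    for (a, b), meandiff, p_adj in zip(pairs, tukey.meandiffs, tukey.pvalues):
        ia, ib = int(a[1:]) - 1, int(b[1:]) - 1
        results.append(StatsResult(
            test_name="tukey-hsd", comparison=f"{a} vs {b}",
            statistic=float(meandiff), p_raw=float(p_adj),
            p_adjusted=float(p_adj), adjustment_method="studentized-range",
            n_per_group=(len(arrays[ia]), len(arrays[ib]))))
    return results


# ---------------------------------------------------------------------------
# Regression and proportions


def linear_regression(x, y) -> RegressionResult:
    """OLS of y on x; slope p value from the t distribution with n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InputError("x and y lengths differ")
    if x.size < 3:
        raise InputError("need at least three points")
    if np.ptp(x) == 0.0:
        raise InputError("x is constant: slope undefined")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue**2), p_slope=float(res.pvalue),
        n=int(x.size))


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> StatsResult:
    """Two-sided pooled-variance z test for two proportions.

    Falls back to Fisher's exact test unless every pooled expected cell
    count exceeds 5 (the usual validity rule for the normal approximation).
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise InputError("sample sizes must be >= 1")
        if not 0 <= k <= n:
            raise InputError("successes must satisfy 0 <= k <= n")
    p_pool = (k1 + k2) / (n1 + n2)
    expected = [n1 * p_pool, n1 * (1 - p_pool), n2 * p_pool, n2 * (1 - p_pool)]
    if min(expected) <= 5:
        _, p = sps.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]],
                                alternative="two-sided")
        return StatsResult(test_name="fisher-exact", comparison="p1 vs p2",
                           statistic=math.nan, p_raw=float(p),
                           n_per_group=(n1, n2))
    p1, p2 = k1 / n1, k2 / n2
    se = math.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    z = 0.0 if se == 0 else (p1 - p2) / se
    p = 2.0 * sps.norm.sf(abs(z))
    return StatsResult(test_name="two-proportion-z (pooled)",
                       comparison="p1 vs p2", statistic=float(z),
                       p_raw=min(1.0, float(p)), n_per_group=(n1, n2))


# ---------------------------------------------------------------------------
# Summary-table aggregation


def _sem(values: np.ndarray) -> float:
    if values.size < 2:
        return float("nan")
    return float(values.std(ddof=1) / math.sqrt(values.size))


def summarize_group(
    fields: pd.DataFrame,
    nuclei: pd.DataFrame,
    group_label: str,
    fields_per_subject: int = FIELDS_PER_SUBJECT,
) -> GroupSummary:
    """Aggregate one group into the summary-table schema.

    Parameters
    ----------
    fields:
        One row per analysed field with ``field_id``, ``subject_id`` and
        ``cell_count`` (fields with zero cells included).
    nuclei:
        One row per nucleus with ``field_id``, ``focus_count`` and optionally
        ``cytoplasmic_count`` (an externally supplied manual count).

    SEM denominators: cells/field over the number of fields; inclusions/cell
    over the number of cells.  Both choices are recorded in ``sem_units``.
    """
    if len(fields) == 0:
        raise InputError("summarize_group needs at least one field")
    cells = fields["cell_count"].to_numpy(dtype=float)
    total = int(cells.sum())
    counts = nuclei["focus_count"].to_numpy(dtype=float) if len(nuclei) else \
        np.array([])
    cyto = None
    if "cytoplasmic_count" in nuclei.columns and len(nuclei):
        cyto = nuclei["cytoplasmic_count"].to_numpy(dtype=float)
    return GroupSummary(
        group_label=group_label,
        n_subjects=int(fields["subject_id"].nunique()),
        total_cells=total,
        mean_cells_per_field=float(cells.mean()),
        sem_cells_per_field=_sem(cells),
        mean_nuclear_inclusions_per_cell=(
            float(counts.mean()) if counts.size else float("nan")),
        sem_nuclear_inclusions_per_cell=_sem(counts),
        mean_cytoplasmic_inclusions_per_cell=(
            float(cyto.mean()) if cyto is not None else None),
        sem_cytoplasmic_inclusions_per_cell=(
            _sem(cyto) if cyto is not None else None),
        n_fields=int(len(fields)),
    )


def mean_cells_per_field_from_totals(total_cells: int, n_subjects: int,
                                     fields_per_subject: int = FIELDS_PER_SUBJECT
                                     ) -> float:
    """Mean cells/field implied by a printed group total (total / (N x 8))."""
    if n_subjects < 1 or fields_per_subject < 1:
        raise InputError("subject and field counts must be >= 1")
    return total_cells / (n_subjects * fields_per_subject)
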