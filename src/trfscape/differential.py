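"""Tumor-vs-normal differential expression of tRFs.

Per-tRF two-sided Mann-Whitney tests with Benjamini-Hochberg correction
within (cohort x tRF class), median-based fold changes, a per-cohort
global expression-shift t-test on class totals, and cross-cohort
dysregulation summaries. A tRF is called up in a cohort when
FDR < 0.01 and fold change > 2 (down: fold change < 0.5).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

# paper-style gates: FDR < 0.01 and fold change > 2 (or < 1/2)
DEFAULT_FDR = 0.01
DEFAULT_FC = 2.0
# "sufficient corresponding normal samples" means n > 15
DEFAULT_MIN_NORMALS = 16
EPS_RPM = 0.01


class DifferentialError(ValueError):
    pass


def _mannwhitney_rows(x: np.ndarray, y: np.ndarray, exact_max_n: int = 25):
    """Row-wise two-sided Mann-Whitney p-values.

    Exact enumeration when both groups are small (<= exact_max_n) and the
    pooled row is tie-free; otherwise the normal approximation with tie
    correction. Returns an array of p-values.
    """
    n1, n2 = x.shape[1], y.shape[1]
    pooled = np.concatenate([x, y], axis=1)
    has_ties = np.array(
        [len(np.unique(row)) < row.size for row in pooled]
    )
    p = np.empty(x.shape[0])
    small = max(n1, n2) <= exact_max_n
    exact_rows = (~has_ties) & small
    if exact_rows.any():
        res = stats.mannwhitneyu(
            x[exact_rows], y[exact_rows], axis=1,
            alternative="two-sided", method="exact",
        )
        p[exact_rows] = res.pvalue
    if (~exact_rows).any():
        res = stats.mannwhitneyu(
            x[~exact_rows], y[~exact_rows], axis=1,
            alternative="two-sided", method="asymptotic",
        )
        p[~exact_rows] = res.pvalue
    return np.clip(p, 0.0, 1.0)


def de_test(
    matrix,
    cohort: str,
    min_normals: int = DEFAULT_MIN_NORMALS,
    fdr_threshold: float = DEFAULT_FDR,
    fc_threshold: float = DEFAULT_FC,
    eps: float = EPS_RPM,
) -> pd.DataFrame:
    """Tumor-vs-normal DE for every tRF of one cohort.

    Fold change = (tumor median RPM + eps) / (normal median RPM + eps).
    BH FDR is computed within (cohort x tRF class). Returns a frame with
    columns trf, cohort, trf_class, fold_change, p_value, fdr, direction.
    Raises :class:`DifferentialError` when the cohort has too few normals.
    """
    sub = matrix.subset(cohort=cohort)
    tumor = sub.condition_mask("tumor")
    normal = sub.condition_mask("normal")
    if len(normal) < min_normals:
        raise DifferentialError(
            f"cohort {cohort}: {len(normal)} normals < required {min_normals}"
        )
    rpm = sub.rpm
    x = rpm[tumor].values
    y = rpm[normal].values
    p = _mannwhitney_rows(x, y)
    fc = (np.median(x, axis=1) + eps) / (np.median(y, axis=1) + eps)
    classes = (
        sub.features["trf_class"]
        if sub.features is not None
        else pd.Series("all", index=rpm.index)
    )
    fdr = np.empty_like(p)
    for cls in classes.unique():
        m = (classes == cls).values
        fdr[m] = stats.false_discovery_control(p[m], method="bh")
    direction = np.where(
        (fdr < fdr_threshold) & (fc > fc_threshold),
        "up",
        np.where((fdr < fdr_threshold) & (fc < 1.0 / fc_threshold), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "trf": rpm.index,
            "cohort": cohort,
            "trf_class": classes.values,
            "fold_change": fc,
            "p_value": p,
            "fdr": fdr,
            "direction": direction,
        }
    ).reset_index(drop=True)


def de_test_all(matrix, cohorts=None, **kwargs) -> pd.DataFrame:
    """Run :func:`de_test` over cohorts, skipping (with a log entry) any
    cohort below the normal-sample floor."""
    results = []
    for cohort in cohorts if cohorts is not None else matrix.cohorts:
        try:
            results.append(de_test(matrix, cohort, **kwargs))
        except DifferentialError as err:
            logger.warning("skipping cohort: %s", err)
    if not results:
        raise DifferentialError("no cohort passed the normal-sample floor")
    return pd.concat(results, ignore_index=True)


def global_shift_test(matrix, cohort: str, trf_class: str,
                      min_normals: int = DEFAULT_MIN_NORMALS):
    """Two-sided t-test of per-sample total class RPM, tumor vs normal.

    Returns ``(p_value, shift)`` where shift is the tumor-minus-normal
    difference of mean totals (sign gives the direction of the global
    expression shift).
    """
    sub = matrix.subset(cohort=cohort, trf_class=trf_class)
    totals = sub.rpm.sum(axis=0)
    t_vals = totals[sub.condition_mask("tumor")].values
    n_vals = totals[sub.condition_mask("normal")].values
    if len(t_vals) < 2 or len(n_vals) < 2:
        raise DifferentialError(
            f"cohort {cohort}: need >=2 samples per condition for the shift test"
        )
    if len(n_vals) < min_normals:
        raise DifferentialError(
            f"cohort {cohort}: {len(n_vals)} normals < required {min_normals}"
        )
    res = stats.ttest_ind(t_vals, n_vals)
    return float(res.pvalue), float(t_vals.mean() - n_vals.mean())


def dysregulation_summary(results: pd.DataFrame):
    """Summarize DE calls across cohorts.

    Returns ``(per_cohort, recurrence)``: per (cohort, class) the fractions
    of tested tRFs called up/down, and per tRF the number of cohorts in
    which it is up or down.
    """
    if results.empty:
        raise DifferentialError("empty DE results")
    grp = results.groupby(["cohort", "trf_class"])
    per_cohort = pd.DataFrame(
        {
            "n_tested": grp.size(),
            "fraction_up": grp.apply(
                lambda g: (g["direction"] == "up").mean(), include_groups=False
            ),
            "fraction_down": grp.apply(
                lambda g: (g["direction"] == "down").mean(), include_groups=False
            ),
        }
    ).reset_index()
    rec = results.pivot_table(
        index="trf",
        columns="direction",
        values="cohort",
        aggfunc="count",
        fill_value=0,
    )
    recurrence = pd.DataFrame(
        {
            "n_cohorts_up": rec.get("up", pd.Series(0, index=rec.index)),
            "n_cohorts_down": rec.get("down", pd.Series(0, index=rec.index)),
        }
    )
    return per_cohort, recurrence
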