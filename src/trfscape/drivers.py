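"""Driver-tRF screen: recurrent tumor upregulation combined with
unfavorable survival via Fisher's method, tissue-specificity scoring and
guilt-by-association co-expression.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .cleavage import CleavageDistribution, js_divergence

logger = logging.getLogger(__name__)


class DriverScreenError(ValueError):
    pass


def fisher_combine(p_values) -> float:
    """Fisher's combined probability: X2 = -2 sum(ln p) ~ chi2(2k)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise DriverScreenError("fisher_combine needs at least one p-value")
    if (p <= 0).any() or (p > 1).any():
        raise DriverScreenError("p-values must lie in (0, 1]")
    x2 = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x2, 2 * p.size))


def survival_split_test(expression: pd.Series, clinical: pd.DataFrame):
    """Median-split survival test for one tRF in one cohort.

    Samples are split at the cohort median expression; returns
    ``(logrank_p, worse_when_high)`` where the direction comes from the
    sign of the Cox coefficient of the high-expression indicator.
    NaN p-value when the fit degenerates.
    """
    from lifelines import CoxPHFitter
    from lifelines.statistics import logrank_test

    shared = expression.index.intersection(clinical.index)
    expr = expression.loc[shared]
    high = (expr > expr.median()).astype(int)
    if high.nunique() < 2:
        return np.nan, False
    df = pd.DataFrame(
        {
            "os_time": clinical.loc[shared, "os_time"].astype(float),
            "os_event": clinical.loc[shared, "os_event"].astype(int),
            "high": high,
        }
    ).dropna()
    if df["high"].nunique() < 2 or df["os_event"].sum() == 0:
        return np.nan, False
    lo, hi = df[df["high"] == 0], df[df["high"] == 1]
    lr = logrank_test(hi["os_time"], lo["os_time"],
                      hi["os_event"], lo["os_event"])
    try:
        cph = CoxPHFitter()
        cph.fit(df, duration_col="os_time", event_col="os_event")
        worse = bool(cph.params_["high"] > 0)
    except Exception:
        worse = bool(hi["os_time"].mean() < lo["os_time"].mean())
    return float(lr.p_value), worse


def screen_drivers(
    de_results: pd.DataFrame,
    matrix,
    min_cohorts: int = 2,
    surv_alpha: float = 0.05,
    bh_alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen for oncogenic driver tRFs.

    A cohort is *qualifying* for a tRF when the tRF is significantly
    upregulated there (DE direction 'up') and its high expression is
    associated with worse survival (median-split log-rank p < surv_alpha
    with an unfavorable hazard direction). tRFs qualifying in at least
    ``min_cohorts`` cohorts get a Fisher-combined P over the qualifying
    cohorts' DE and survival p-values; drivers are called by BH across all
    tested tRFs (non-candidates carry p = 1, keeping the rejection set
    monotone when ``min_cohorts`` is relaxed) at ``bh_alpha``.

    ``matrix`` must carry os_time/os_event in its sample metadata.
    """
    if "os_time" not in matrix.samples.columns:
        raise DriverScreenError("no survival data in sample metadata")
    rpm = matrix.rpm
    samples = matrix.samples
    records = []
    up = de_results[de_results["direction"] == "up"]
    surv_cache: dict[tuple[str, str], tuple[float, bool]] = {}
    for trf, grp in up.groupby("trf"):
        per_cohort = {}
        n_up = 0
        n_risky = 0
        qualifying = []
        for _, row in grp.iterrows():
            cohort = row["cohort"]
            n_up += 1
            key = (trf, cohort)
            if key not in surv_cache:
                tumors = samples.index[
                    (samples["cohort"] == cohort) & (samples["condition"] == "tumor")
                ]
                clin = samples.loc[tumors, ["os_time", "os_event"]]
                surv_cache[key] = survival_split_test(rpm.loc[trf, tumors], clin)
            surv_p, worse = surv_cache[key]
            per_cohort[cohort] = {
                "de_p": row["p_value"], "surv_p": surv_p, "worse": worse,
            }
            if np.isfinite(surv_p) and surv_p < surv_alpha and worse:
                n_risky += 1
                qualifying.append((row["p_value"], surv_p))
        if len(qualifying) >= min_cohorts:
            p_comb = fisher_combine(
                [p for pair in qualifying for p in pair]
            )
        else:
            p_comb = np.nan
        records.append(
            {
                "trf": trf,
                "n_cohorts_up": n_up,
                "n_cohorts_risky": n_risky,
                "p_comb": p_comb,
                "per_cohort": per_cohort,
            }
        )
    all_trfs = de_results["trf"].unique()
    tested = {r["trf"] for r in records}
    for trf in all_trfs:
        if trf not in tested:
            records.append(
                {
                    "trf": trf, "n_cohorts_up": 0, "n_cohorts_risky": 0,
                    "p_comb": np.nan, "per_cohort": {},
                }
            )
    out = pd.DataFrame(records).set_index("trf")
    p_for_bh = out["p_comb"].fillna(1.0).clip(upper=1.0).values
    fdr = stats.false_discovery_control(p_for_bh, method="bh")
    out["fdr"] = fdr
    out["is_driver"] = out["p_comb"].notna() & (out["fdr"] < bh_alpha)
    return out.sort_values("p_comb")


def tissue_specificity(matrix) -> pd.Series:
    """Per-tRF tissue (cohort) specificity as a JS score in [0, 1].

    The distribution of a tRF's mean RPM across cohorts is compared with
    the uniform distribution by JS divergence; 0 = equally expressed
    everywhere. tRFs with zero expression in every cohort are reported
    missing (NaN). Invariant to cohort order and to rescaling.
    """
    cohorts = matrix.cohorts
    if len(cohorts) < 2:
        raise DriverScreenError("tissue specificity needs >=2 cohorts")
    means = pd.DataFrame(
        {
            ch: matrix.rpm[
                matrix.samples.index[matrix.samples["cohort"] == ch]
            ].mean(axis=1)
            for ch in sorted(cohorts)
        }
    )
    labels = tuple(means.columns)
    uniform = CleavageDistribution.uniform(labels)
    scores = {}
    for trf, row in means.iterrows():
        total = row.sum()
        if total <= 0:
            scores[trf] = np.nan
            continue
        d = CleavageDistribution(labels, (row / total).values)
        scores[trf] = js_divergence(d, uniform)
    return pd.Series(scores, name="tissue_js")


def _spearman_columns(x: np.ndarray, y: np.ndarray):
    """Spearman rho and two-sided p of vector ``x`` against each column of
    ``y`` (t approximation), vectorized."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y, axis=0)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean(axis=0)) / np.where(ry.std(axis=0) == 0, 1, ry.std(axis=0))
    rho = (ry * rx[:, None]).mean(axis=0)
    rho = np.clip(rho, -0.999999, 0.999999)
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    return rho, p


def coexpression(
    trf_expression: pd.Series,
    gene_expression: pd.DataFrame,
    cohort_of: pd.Series,
    min_cohorts: int = 8,
    fdr_alpha: float = 0.05,
    min_rho: float = 0.3,
    min_samples: int = 10,
) -> pd.DataFrame:
    """Guilt-by-association co-expression across cohorts.

    Per cohort, Spearman correlation of each gene against the tRF with BH
    correction across genes; a gene is *reported* when it is significant
    (FDR < ``fdr_alpha`` and |rho| >= ``min_rho``) with a consistent sign
    in at least ``min_cohorts`` cohorts. Cohorts with fewer than
    ``min_samples`` shared samples are skipped.
    """
    genes = gene_expression.index
    n_pos = pd.Series(0, index=genes)
    n_neg = pd.Series(0, index=genes)
    n_cohorts_used = 0
    for cohort in sorted(cohort_of.unique()):
        cols = cohort_of.index[cohort_of == cohort]
        cols = cols.intersection(trf_expression.index).intersection(
            gene_expression.columns
        )
        if len(cols) < min_samples:
            logger.warning("cohort %s has <%d shared samples; skipped",
                           cohort, min_samples)
            continue
        n_cohorts_used += 1
        rho, p = _spearman_columns(
            trf_expression.loc[cols].values,
            gene_expression[cols].T.values,
        )
        fdr = stats.false_discovery_control(np.clip(p, 0, 1), method="bh")
        sig = (fdr < fdr_alpha) & (np.abs(rho) >= min_rho)
        n_pos += pd.Series(sig & (rho > 0), index=genes).astype(int)
        n_neg += pd.Series(sig & (rho < 0), index=genes).astype(int)
    if n_cohorts_used == 0:
        raise DriverScreenError("no cohort with enough shared samples")
    out = pd.DataFrame(
        {
            "n_cohorts_positive": n_pos,
            "n_cohorts_negative": n_neg,
        }
    )
    out["reported"] = (out["n_cohorts_positive"] >= min_cohorts) | (
        out["n_cohorts_negative"] >= min_cohorts
    )
    return out
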