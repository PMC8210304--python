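"""Expression subtyping within a cohort and survival analysis.

NMF consensus clustering (multiplicative KL updates from many random
starts), cophenetic-correlation rank selection, t-statistic signature
extraction, nearest-centroid projection onto validation cohorts, and
Kaplan-Meier / log-rank / Cox proportional-hazards analysis of the
resulting patient groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform
from sklearn.decomposition import NMF

logger = logging.getLogger(__name__)


class SubtypingError(ValueError):
    pass


def preprocess_for_nmf(rpm: pd.DataFrame) -> pd.DataFrame:
    """log2(RPM+1) then per-tRF minimum subtraction (keeps non-negativity);
    constant rows are dropped."""
    x = np.log2(rpm + 1.0)
    x = x.sub(x.min(axis=1), axis=0)
    return x.loc[x.max(axis=1) > 0]


@dataclass
class SubtypeModel:
    cohort: str | None
    trf_class: str | None
    k: int
    assignments: pd.Series  # sample -> subtype label (1..k)
    consensus: pd.DataFrame  # sample x sample co-assignment frequency
    cophenetic: dict[int, float]  # candidate k -> cophenetic correlation
    feature_matrix: pd.DataFrame = field(repr=False, default=None)


def _consensus_for_k(x: np.ndarray, k: int, n_runs: int, seeds) -> np.ndarray:
    """Co-assignment frequency over ``n_runs`` NMF factorizations.

    ``x`` is samples x features (non-negative). Each run assigns a sample
    to the argmax column of its W row.
    """
    n = x.shape[0]
    consensus = np.zeros((n, n))
    for seed in seeds:
        model = NMF(
            n_components=k,
            init="random",
            solver="mu",
            beta_loss="kullback-leibler",
            max_iter=2000,
            tol=1e-6,
            random_state=int(seed),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w = model.fit_transform(x)
        labels = np.argmax(w, axis=1)
        consensus += labels[:, None] == labels[None, :]
    return consensus / len(seeds)


def _cophenetic_correlation(consensus: np.ndarray):
    dist = squareform(1.0 - consensus, checks=False)
    link = average(dist)
    coph, _ = cophenet(link, dist)
    return float(coph), link


def nmf_consensus(
    matrix,
    cohort: str | None = None,
    trf_class: str | None = None,
    k_range=(2, 6),
    n_runs: int = 50,
    seed: int = 0,
) -> SubtypeModel:
    """NMF consensus clustering of samples by tRF expression.

    For each candidate rank k the consensus (co-assignment) matrix over
    ``n_runs`` random restarts is built; the chosen k maximizes the
    cophenetic correlation of average-linkage clustering on 1-consensus,
    and final subtype labels come from cutting that tree into k groups.
    Deterministic under a fixed seed and invariant to sample order
    (samples are canonically sorted before fitting).
    """
    sub = matrix.subset(cohort=cohort, trf_class=trf_class)
    x = preprocess_for_nmf(sub.rpm)
    if x.empty:
        raise SubtypingError("no informative tRFs for NMF")
    if (x.values < 0).any():
        raise SubtypingError("NMF input must be non-negative")
    x = x[sorted(x.columns)]
    data = np.ascontiguousarray(x.values.T)  # samples x features
    ks = list(range(k_range[0], k_range[1] + 1))
    if data.shape[0] <= max(ks):
        raise SubtypingError("fewer samples than the largest candidate k")
    ss = np.random.SeedSequence(seed)
    run_seeds = ss.generate_state(len(ks) * n_runs).reshape(len(ks), n_runs)
    coph_by_k, consensus_by_k, link_by_k = {}, {}, {}
    for i, k in enumerate(ks):
        consensus = _consensus_for_k(data, k, n_runs, run_seeds[i] % (2**31 - 1))
        coph, link = _cophenetic_correlation(consensus)
        coph_by_k[k] = coph
        consensus_by_k[k] = consensus
        link_by_k[k] = link
    # rank choice: maximum cophenetic correlation; exact ties (several k
    # perfectly stable) resolve to the largest such k
    top = max(coph_by_k.values())
    best_k = max(k for k in ks if coph_by_k[k] >= top - 1e-6)
    raw = fcluster(link_by_k[best_k], best_k, criterion="maxclust")
    # deterministic label order: 1..k by first appearance along sorted samples
    seen: dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in seen:
            seen[r] = len(seen) + 1
        labels.append(seen[r])
    assignments = pd.Series(labels, index=x.columns, name="subtype")
    consensus = pd.DataFrame(
        consensus_by_k[best_k], index=x.columns, columns=x.columns
    )
    return SubtypeModel(
        cohort=cohort,
        trf_class=trf_class,
        k=best_k,
        assignments=assignments,
        consensus=consensus,
        cophenetic=coph_by_k,
        feature_matrix=x,
    )


def subtype_t_scores(values: pd.DataFrame, assignments: pd.Series) -> pd.DataFrame:
    """t-statistic of each feature in each subtype vs all other samples.

    ``values`` is feature x sample. Zero-variance contrasts give t = 0.
    Returns feature x subtype.
    """
    values = values[assignments.index]
    out = {}
    for subtype in sorted(assignments.unique()):
        mask = (assignments == subtype).values
        if mask.sum() < 2 or (~mask).sum() < 2:
            out[subtype] = np.zeros(len(values))
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(
                values.values[:, mask], values.values[:, ~mask], axis=1
            )
        out[subtype] = np.nan_to_num(res.statistic)
    return pd.DataFrame(out, index=values.index)


@dataclass
class SignatureSet:
    trf_class: str | None
    signatures: dict[int, list[tuple[str, float]]]  # subtype -> [(trf, score)]
    centroids: pd.DataFrame  # signature tRF x subtype (standardized means)
    scaler: pd.DataFrame  # per-tRF mean/sd used for standardization
    length_summary: dict[int, tuple[int, int]]

    @property
    def all_trfs(self) -> list[str]:
        return list(self.centroids.index)


def extract_signatures(
    model: SubtypeModel,
    matrix,
    t_threshold: float = 3.0,
    fdr_threshold: float = 0.05,
) -> SignatureSet:
    """Subtype-specific tRF signatures by a t-score schema.

    Each tRF gets a t-statistic per subtype (that subtype vs the rest, on
    log2 RPM); it is assigned to its best subtype when |t| passes the score
    threshold and the BH FDR across tRFs passes 0.05. Subtypes with fewer
    than 3 samples are suppressed. Signatures are sorted by descending
    score; per-subtype fragment-size ranges are summarized.
    """
    sub = matrix.subset(trf_class=model.trf_class, samples=model.assignments.index)
    logx = np.log2(sub.rpm + 1.0)
    tscores = subtype_t_scores(logx, model.assignments)
    n1 = model.assignments.value_counts()
    n = len(model.assignments)
    signatures: dict[int, list[tuple[str, float]]] = {
        s: [] for s in sorted(model.assignments.unique())
    }
    best = tscores.idxmax(axis=1)
    best_t = tscores.max(axis=1)
    df_dof = n - 2
    pvals = 2 * stats.t.sf(np.abs(best_t.values), df_dof)
    fdr = stats.false_discovery_control(np.clip(pvals, 0, 1), method="bh")
    fdr = pd.Series(fdr, index=best_t.index)
    for trf in tscores.index:
        s = best[trf]
        if n1.get(s, 0) < 3:
            continue
        if best_t[trf] >= t_threshold and fdr[trf] < fdr_threshold:
            signatures[s].append((trf, float(best_t[trf])))
    for s in signatures:
        if n1.get(s, 0) < 3:
            logger.warning("subtype %s has <3 samples; signatures suppressed", s)
            signatures[s] = []
        signatures[s].sort(key=lambda kv: -kv[1])
    sig_trfs = [t for sig in signatures.values() for t, _ in sig]
    mean = logx.mean(axis=1)
    sd = logx.std(axis=1, ddof=0).replace(0, 1.0)
    z = logx.sub(mean, axis=0).div(sd, axis=0)
    centroids = pd.DataFrame(
        {
            s: z.loc[sig_trfs, model.assignments.index[model.assignments == s]].mean(
                axis=1
            )
            for s in signatures
        }
    )
    lengths = sub.features["length"] if sub.features is not None else None
    length_summary = {}
    for s, sig in signatures.items():
        if sig and lengths is not None:
            ls = [int(lengths[t]) for t, _ in sig]
            length_summary[s] = (min(ls), max(ls))
        else:
            length_summary[s] = (0, 0)
    return SignatureSet(
        trf_class=model.trf_class,
        signatures=signatures,
        centroids=centroids,
        scaler=pd.DataFrame({"mean": mean[sig_trfs], "sd": sd[sig_trfs]}),
        length_summary=length_summary,
    )


def project_signatures(signatures: SignatureSet, validation) -> pd.Series:
    """Assign validation samples to the discovery subtypes.

    Each validation sample (standardized per tRF within the validation
    cohort) goes to the subtype whose signature centroid is nearest by
    Pearson correlation. Warns below 80% signature coverage; errors when
    no signature tRF is shared.
    """
    shared = [t for t in signatures.all_trfs if t in validation.rpm.index]
    if not shared:
        raise SubtypingError("validation matrix shares no signature tRFs")
    coverage = len(shared) / len(signatures.all_trfs)
    if coverage < 0.8:
        logger.warning("only %.0f%% of signature tRFs present in validation",
                       100 * coverage)
    logx = np.log2(validation.rpm.loc[shared] + 1.0)
    sd = logx.std(axis=1, ddof=0).replace(0, 1.0)
    z = logx.sub(logx.mean(axis=1), axis=0).div(sd, axis=0)
    cent = signatures.centroids.loc[shared]
    corr = pd.DataFrame(index=z.columns, columns=cent.columns, dtype=float)
    for s in cent.columns:
        c = cent[s].values
        cc = c - c.mean()
        denom_c = np.sqrt((cc**2).sum())
        zz = z.values - z.values.mean(axis=0)
        denom_z = np.sqrt((zz**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr[s] = (zz * cc[:, None]).sum(axis=0) / (denom_z * denom_c)
    return corr.astype(float).idxmax(axis=1).rename("subtype")


@dataclass
class SurvivalResult:
    groups: list
    logrank_p: float
    hazard_ratios: dict  # contrast -> dict(hr, ci_low, ci_high, p)
    covariates: list
    km_curves: dict = field(repr=False, default=None)


def survival_analysis(
    assignments: pd.Series,
    clinical: pd.DataFrame,
    covariates=None,
    reference_group=None,
    subset=None,
) -> SurvivalResult:
    """Kaplan-Meier + log-rank + Cox PH analysis of subtype groups.

    ``clinical`` must carry ``os_time`` (>0) and ``os_event`` (0/1) indexed
    by sample. ``covariates`` (e.g. stage, ssign) enter the Cox model as
    additional terms; hazard ratios contrast each subtype against
    ``reference_group`` (default: smallest label). ``subset`` restricts the
    analysis (e.g. to early-stage patients). Groups in which the Cox fit is
    degenerate (all censored) report missing hazard ratios.
    """
    from lifelines import CoxPHFitter, KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    shared = assignments.index.intersection(clinical.index)
    if subset is not None:
        shared = shared.intersection(pd.Index(subset))
    df = pd.DataFrame(
        {
            "group": assignments.loc[shared],
            "os_time": clinical.loc[shared, "os_time"].astype(float),
            "os_event": clinical.loc[shared, "os_event"].astype(int),
        }
    ).dropna()
    if (df["os_time"] <= 0).any():
        raise SubtypingError("survival times must be positive")
    counts = df["group"].value_counts()
    if (counts < 2).any() or len(counts) < 2:
        raise SubtypingError("each group needs >=2 samples for survival analysis")
    groups = sorted(df["group"].unique())
    lr = multivariate_logrank_test(df["os_time"], df["group"], df["os_event"])
    km_curves = {}
    for g in groups:
        kmf = KaplanMeierFitter()
        sel = df["group"] == g
        kmf.fit(df.loc[sel, "os_time"], df.loc[sel, "os_event"], label=str(g))
        km_curves[g] = kmf
    reference = reference_group if reference_group is not None else groups[0]
    design = pd.get_dummies(
        df["group"].astype("category"), prefix="grp", dtype=float
    ).drop(columns=[f"grp_{reference}"])
    cox_df = pd.concat([df[["os_time", "os_event"]], design], axis=1)
    cov_cols = []
    if covariates:
        for cov in covariates:
            cox_df[cov] = pd.to_numeric(clinical.loc[df.index, cov], errors="coerce")
            cov_cols.append(cov)
        cox_df = cox_df.dropna()
    hazard_ratios = {}
    try:
        cph = CoxPHFitter()
        cph.fit(cox_df, duration_col="os_time", event_col="os_event")
        summ = cph.summary
        for g in groups:
            col = f"grp_{g}"
            if col in summ.index:
                hazard_ratios[f"{g}_vs_{reference}"] = {
                    "hr": float(summ.loc[col, "exp(coef)"]),
                    "ci_low": float(summ.loc[col, "exp(coef) lower 95%"]),
                    "ci_high": float(summ.loc[col, "exp(coef) upper 95%"]),
                    "p": float(summ.loc[col, "p"]),
                }
    except Exception as err:  # degenerate groups (e.g. all censored)
        logger.warning("Cox fit failed (%s); hazard ratios reported missing", err)
        for g in groups:
            if g != reference:
                hazard_ratios[f"{g}_vs_{reference}"] = {
                    "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                }
    return SurvivalResult(
        groups=groups,
        logrank_p=float(lr.p_value),
        hazard_ratios=hazard_ratios,
        covariates=cov_cols,
        km_curves=km_curves,
    )
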