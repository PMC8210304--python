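"""Cross-cancer subtype analysis: the subtype-activity matrix, superclusters
("clusters of clusters" shared across tumor types), and rank-based
single-sample gene-set enrichment (ssGSEA) for signature activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .simulate import SIZE_CLASS_BINS, size_class_of
from .subtyping import SubtypeModel, subtype_t_scores

logger = logging.getLogger(__name__)


class PancancerError(ValueError):
    pass


def build_activity_matrix(
    matrices: dict,
    models: dict[str, SubtypeModel],
    min_cohorts: int | None = None,
    trf_class: str | None = None,
) -> pd.DataFrame:
    """tRF x (cohort, subtype) matrix of subtype-vs-rest t-scores.

    Features must be present (post-filter) in at least ``min_cohorts``
    cohorts (default: all but two, the 13-of-15 analogue); a feature absent
    from a cohort contributes a neutral 0 there. Cohorts without a fitted
    model are skipped with a log entry. t-scores are computed on per-cohort
    standardized log2(RPM+1).
    """
    cohorts = sorted(matrices)
    fitted = [c for c in cohorts if c in models]
    for c in cohorts:
        if c not in models:
            logger.warning("cohort %s lacks a fitted subtype model; skipped", c)
    if not fitted:
        raise PancancerError("no cohort with a fitted subtype model")
    if min_cohorts is None:
        min_cohorts = max(1, len(fitted) - 2)
    presence: dict[str, int] = {}
    per_cohort_feats = {}
    for c in fitted:
        sub = matrices[c].subset(trf_class=trf_class)
        feats = sub.rpm.index
        per_cohort_feats[c] = sub
        for t in feats:
            presence[t] = presence.get(t, 0) + 1
    feature_set = sorted(t for t, n in presence.items() if n >= min_cohorts)
    if not feature_set:
        raise PancancerError(f"no tRF present in >= {min_cohorts} cohorts")
    blocks = {}
    for c in fitted:
        sub = per_cohort_feats[c]
        model = models[c]
        logx = np.log2(sub.rpm[model.assignments.index] + 1.0)
        sd = logx.std(axis=1, ddof=0).replace(0, 1.0)
        z = logx.sub(logx.mean(axis=1), axis=0).div(sd, axis=0)
        t = subtype_t_scores(z, model.assignments)
        t = t.reindex(feature_set).fillna(0.0)
        for s in t.columns:
            blocks[(c, s)] = t[s]
    activity = pd.DataFrame(blocks)
    activity.columns = pd.MultiIndex.from_tuples(
        activity.columns, names=["cohort", "subtype"]
    )
    return activity


def supercluster(
    activity: pd.DataFrame,
    n_clusters: int = 3,
    lengths: pd.Series | None = None,
    signature_t: float = 2.0,
):
    """Cluster subtype columns into superclusters shared across cohorts.

    Hierarchical clustering with correlation distance (1 - Pearson) and
    average linkage on the activity columns; invariant to column order.
    When per-tRF ``lengths`` are given, each supercluster is summarized by
    the fragment-size-class composition of its member subtypes' signatures
    (features with t-score > ``signature_t``) and the modal size class.

    Returns ``(labels, composition, modal)``.
    """
    if activity.shape[1] < n_clusters:
        raise PancancerError("fewer subtypes than requested superclusters")
    cols = sorted(activity.columns)
    data = activity[cols].values.astype(float)
    corr = np.corrcoef(data.T)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = squareform(np.clip(1.0 - corr, 0.0, 2.0), checks=False)
    link = average(dist)
    raw = fcluster(link, n_clusters, criterion="maxclust")
    seen: dict[int, int] = {}
    labels = pd.Series(
        [seen.setdefault(r, len(seen) + 1) for r in raw],
        index=pd.MultiIndex.from_tuples(cols, names=["cohort", "subtype"]),
        name="supercluster",
    )
    composition = modal = None
    if lengths is not None:
        classes = list(SIZE_CLASS_BINS)
        rows = {}
        for sc in sorted(labels.unique()):
            members = labels.index[labels == sc]
            tally = dict.fromkeys(classes, 0.0)
            for col in members:
                sig = activity.index[activity[col] > signature_t]
                for trf in sig:
                    if trf in lengths.index:
                        tally[size_class_of(int(lengths[trf]))] += 1.0
            total = sum(tally.values())
            rows[sc] = {
                c: (tally[c] / total if total else 1.0 / len(classes))
                for c in classes
            }
        composition = pd.DataFrame(rows).T
        composition.index.name = "supercluster"
        modal = composition.idxmax(axis=1).rename("modal_size_class")
    return labels, composition, modal


def ssgsea(
    expression: pd.DataFrame,
    gene_sets: dict[str, list],
    exponent: float = 0.25,
    min_size: int = 5,
    normalize: bool = False,
    center: bool = True,
) -> pd.DataFrame:
    """Single-sample gene-set enrichment (rank-weighted ECDF difference).

    Per sample, genes are ranked by expression; the enrichment score is the
    sum over the ranked list of the difference between the weighted in-set
    ECDF (ranks raised to ``exponent``) and the unweighted out-of-set ECDF.
    Deterministic and invariant to strictly monotone transforms of the
    expression profile. Sets with fewer than ``min_size`` genes present are
    skipped with a log entry. ``normalize=True`` divides by N - n_set.

    Because ranks and weights are correlated, the raw running sum has a
    positive offset even for randomly placed sets; by default
    (``center=True``) the sample's expected baseline -- the same running sum
    with every gene weighted as a fractional set member -- is subtracted so
    that random sets score near 0 and scores are comparable across sets.
    """
    genes = expression.index
    n = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    scores = {}
    ranks = rankdata(expression.values, axis=0)  # 1 = lowest expression
    order = np.argsort(-expression.values, axis=0, kind="stable")
    for name, members in gene_sets.items():
        member_idx = np.array(
            sorted({gene_pos[g] for g in members if g in gene_pos}), dtype=int
        )
        if len(member_idx) < min_size:
            logger.warning("gene set %s has <%d genes present; skipped",
                           name, min_size)
            continue
        in_set = np.zeros(n, dtype=bool)
        in_set[member_idx] = True
        set_scores = np.empty(expression.shape[1])
        n_out = n - len(member_idx)
        for j in range(expression.shape[1]):
            ordered_in = in_set[order[:, j]]
            w_all = ranks[order[:, j], j] ** exponent
            w = np.where(ordered_in, w_all, 0.0)
            cum_in = np.cumsum(w)
            denom = cum_in[-1]
            p_in = cum_in / denom if denom > 0 else np.zeros(n)
            p_out = np.cumsum(~ordered_in) / n_out
            es = float((p_in - p_out).sum())
            if center:
                baseline = np.cumsum(w_all) / w_all.sum()
                es -= float((baseline - p_out).sum())
            set_scores[j] = es / (n - len(member_idx)) if normalize else es
        scores[name] = set_scores
    if not scores:
        raise PancancerError("no usable gene set (all below min_size)")
    return pd.DataFrame(scores, index=expression.columns).T


@dataclass
class SignatureActivityResult:
    t_scores: pd.DataFrame  # signature x (cohort, subtype)
    ranking: dict  # supercluster -> signatures ranked by 25th-quantile t
    top_program: dict  # supercluster -> program name (or None on tie)


def signature_activity(
    scores: pd.DataFrame,
    models: dict[str, SubtypeModel],
    program_map: pd.Series,
    superclusters: pd.Series | None = None,
    top_n: int = 50,
) -> SignatureActivityResult:
    """Program-level characterization of subtypes from ssGSEA scores.

    Per cohort, each signature's activation is contrasted subtype-vs-rest
    with a t-score. Within each supercluster signatures are ranked by the
    25th quantile of their t-scores across member subtypes (descending) and
    the most enriched gene program is called by majority over the top
    ``top_n`` signatures (ties reported as None).
    """
    blocks = {}
    for c, model in sorted(models.items()):
        cols = [s for s in model.assignments.index if s in scores.columns]
        if not cols:
            continue
        t = subtype_t_scores(scores[cols], model.assignments.loc[cols])
        for s in t.columns:
            blocks[(c, s)] = t[s]
    if not blocks:
        raise PancancerError("no overlap between ssGSEA samples and subtype models")
    tmat = pd.DataFrame(blocks)
    tmat.columns = pd.MultiIndex.from_tuples(tmat.columns,
                                             names=["cohort", "subtype"])
    ranking: dict = {}
    top_program: dict = {}
    if superclusters is None:
        superclusters = pd.Series(1, index=tmat.columns)
    for sc in sorted(superclusters.unique()):
        members = [c for c in superclusters.index[superclusters == sc]
                   if c in tmat.columns]
        if not members:
            continue
        q25 = tmat[members].quantile(0.25, axis=1)
        ranked = q25.sort_values(ascending=False)
        ranking[sc] = ranked
        top = ranked.head(top_n).index
        progs = program_map.reindex(top).dropna()
        if progs.empty or ranked.abs().max() == 0:
            top_program[sc] = None
            continue
        counts = progs.value_counts()
        if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
            top_program[sc] = None  # tie
        else:
            top_program[sc] = counts.index[0]
    return SignatureActivityResult(t_scores=tmat, ranking=ranking,
                                   top_program=top_program)


def overlap_fraction(assign_a: pd.Series, assign_b: pd.Series) -> pd.DataFrame:
    """Row-normalized contingency table between two sample groupings."""
    shared = assign_a.index.intersection(assign_b.index)
    if shared.empty:
        raise PancancerError("groupings share no samples")
    return pd.crosstab(
        assign_a.loc[shared], assign_b.loc[shared], normalize="index"
    )
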