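"""Cleavage-pattern statistics: size profiles, position landscapes and the
entropy-based Jensen-Shannon (JS) cleavage score.

The JS cleavage score compares discrete probability distributions over
fragment sizes (or cleavage positions). With base-2 entropy the pairwise
score

    JS(e1, e2) = H((e1 + e2) / 2) - (H(e1) + H(e2)) / 2

lies in [0, 1]: 0 means the two cleavage patterns are identical and 1 means
they have disjoint support. For more than two distributions the score
generalizes to H(mean) - mean(H) normalized by log2(n), which preserves the
[0, 1] range and reduces exactly to the pairwise form at n = 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

_NORM_ATOL = 1e-8


class CleavageError(ValueError):
    pass


@dataclass(frozen=True)
class CleavageDistribution:
    """A probability distribution over cleavage sizes or positions."""

    labels: tuple
    e: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.e, dtype=float)
        object.__setattr__(self, "e", e)
        object.__setattr__(self, "labels", tuple(self.labels))
        if e.ndim != 1 or len(e) != len(self.labels):
            raise CleavageError("labels and probabilities must align")
        if (e < -1e-12).any() or (e > 1 + 1e-12).any():
            raise CleavageError("probabilities outside [0, 1]")
        if abs(e.sum() - 1.0) > _NORM_ATOL:
            raise CleavageError(f"distribution sums to {e.sum():.6g}, not 1")

    @classmethod
    def from_counts(cls, labels, values) -> "CleavageDistribution":
        v = np.asarray(values, dtype=float)
        total = v.sum()
        if total <= 0:
            raise CleavageError("cannot normalize an all-zero vector")
        return cls(tuple(labels), v / total)

    @classmethod
    def uniform(cls, labels) -> "CleavageDistribution":
        labels = tuple(labels)
        return cls(labels, np.full(len(labels), 1.0 / len(labels)))

    @classmethod
    def point_mass(cls, labels, at) -> "CleavageDistribution":
        labels = tuple(labels)
        e = np.zeros(len(labels))
        e[labels.index(at)] = 1.0
        return cls(labels, e)


def _entropy_bits(p: np.ndarray) -> float:
    """Shannon entropy in bits with the 0*log(0) := 0 convention."""
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def shannon_entropy(d: CleavageDistribution) -> float:
    """Shannon entropy of a cleavage distribution, in bits."""
    return _entropy_bits(d.e)


def _check_labels(*ds: CleavageDistribution):
    labels = ds[0].labels
    for d in ds[1:]:
        if d.labels != labels:
            raise CleavageError("distributions are over different labels")


def js_divergence(d1: CleavageDistribution, d2: CleavageDistribution) -> float:
    """Pairwise Jensen-Shannon divergence, base 2, in [0, 1]."""
    _check_labels(d1, d2)
    mix = (d1.e + d2.e) / 2.0
    return _entropy_bits(mix) - (_entropy_bits(d1.e) + _entropy_bits(d2.e)) / 2.0


def js_cleavage_score(ds, method: str = "generalized") -> float:
    """JS cleavage score of >=2 distributions over the same labels.

    ``method='generalized'`` (default): (H(mean) - mean(H)) / log2(n), which
    equals the pairwise JS divergence at n = 2. ``method='cabili'`` takes
    the JS-distance analogue sqrt(generalized); both are 0 iff all
    distributions are identical and 1 for mutually disjoint point masses.
    """
    ds = list(ds)
    if len(ds) < 2:
        raise CleavageError("js_cleavage_score needs at least two distributions")
    _check_labels(*ds)
    stack = np.stack([d.e for d in ds])
    mean = stack.mean(axis=0)
    score = _entropy_bits(mean) - np.mean([_entropy_bits(e) for e in stack])
    score /= np.log2(len(ds))
    score = float(min(max(score, 0.0), 1.0))
    if method == "generalized":
        return score
    if method == "cabili":
        return float(np.sqrt(score))
    raise CleavageError(f"unknown method {method!r}")


def size_labels(length_range=(15, 30)) -> tuple:
    return tuple(range(length_range[0], length_range[1] + 1))


def size_profile(matrix, trf_class: str, group_by: str = "cohort",
                 length_range=(15, 30)) -> dict[str, CleavageDistribution]:
    """Per-group size profile: the average over samples of each sample's
    normalized RPM-by-fragment-size vector for one tRF class.

    ``group_by`` names a column of ``matrix.samples`` (cohort, condition,
    tissue...). Samples with zero class expression are skipped.
    """
    if matrix.features is None:
        raise CleavageError("matrix lacks feature metadata (length, class)")
    labels = size_labels(length_range)
    sub = matrix.subset(trf_class=trf_class)
    lengths = sub.features["length"]
    by_size = sub.rpm.groupby(lengths).sum()  # size x sample
    by_size = by_size.reindex(list(labels), fill_value=0.0)
    groups = matrix.samples[group_by]
    profiles = {}
    for group in sorted(groups.unique()):
        cols = [s for s in by_size.columns if groups.get(s) == group]
        vecs = []
        for s in cols:
            v = by_size[s].values
            if v.sum() > 0:
                vecs.append(v / v.sum())
        if not vecs:
            continue
        mean = np.mean(vecs, axis=0)
        profiles[group] = CleavageDistribution(labels, mean / mean.sum())
    return profiles


def position_landscape(matrix, trf_class: str, length_range=(15, 30)):
    """Per-tRNA-family cleavage landscape at one end of the mature tRNA.

    For each family the mean-RPM mass of its fragments is distributed over
    fragment sizes (equivalently cleavage positions: size L from the 5' end
    is a cut after mature base L; from the 3' end, L bases upstream of the
    last CCA base). Families with zero mass are excluded (logged).

    Returns ``(landscape, concentration)``: a family x size DataFrame of
    probabilities and a per-family concentration score
    ``js_divergence(observed, uniform)`` -- higher means cleavage is
    concentrated on few positions.
    """
    import logging

    logger = logging.getLogger(__name__)
    if matrix.features is None:
        raise CleavageError("matrix lacks feature metadata")
    labels = size_labels(length_range)
    sub = matrix.subset(trf_class=trf_class)
    mean_rpm = sub.rpm.mean(axis=1)
    feats = sub.features
    naming_family = feats["parents"].str.split(";").str[0]
    df = pd.DataFrame(
        {"family": naming_family, "length": feats["length"], "mass": mean_rpm}
    )
    pivot = df.pivot_table(index="family", columns="length", values="mass",
                           aggfunc="sum", fill_value=0.0)
    pivot = pivot.reindex(columns=list(labels), fill_value=0.0)
    totals = pivot.sum(axis=1)
    zero = totals.index[totals <= 0]
    for fam in zero:
        logger.info("family %s has zero %s mass; excluded from landscape",
                    fam, trf_class)
    pivot = pivot.loc[totals > 0]
    landscape = pivot.div(pivot.sum(axis=1), axis=0)
    uniform = CleavageDistribution.uniform(labels)
    concentration = pd.Series(
        {
            fam: js_divergence(CleavageDistribution(labels, row.values), uniform)
            for fam, row in landscape.iterrows()
        },
        name="concentration",
        dtype=float,
    )
    return landscape, concentration


def call_hotspots(concentration: pd.Series, threshold: float = 0.5) -> pd.Series:
    """Flag tRNAs whose cleavage concentration exceeds the hotspot cutoff."""
    return concentration >= threshold


def cluster_cleavage_patterns(landscape: pd.DataFrame, k: int = 4,
                              seed: int = 0, n_init: int = 25):
    """Group tRNAs by cleavage pattern with k-means on probability vectors.

    Rows are canonically sorted before fitting, so the clustering is
    invariant to input row order under a fixed seed. Returns ``(labels,
    order)``: cluster label per family and a display ordering grouping
    families by cluster (clusters sorted by mean modal position) and modal
    position within cluster.
    """
    if k < 2:
        raise CleavageError("k must be >= 2")
    if k > len(landscape):
        raise CleavageError(f"k={k} exceeds number of tRNAs ({len(landscape)})")
    data = landscape.sort_index()
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(data.values)
    modal = data.columns.values[np.argmax(data.values, axis=1)]
    modal = pd.Series(modal, index=data.index, dtype=float)
    cluster_modal = pd.Series(modal.values).groupby(raw).mean()
    # relabel clusters 0..k-1 by ascending mean modal position (deterministic)
    order_of = {old: new for new, old in enumerate(cluster_modal.sort_values().index)}
    labels = pd.Series([order_of[c] for c in raw], index=data.index, name="cluster")
    order = (
        pd.DataFrame({"cluster": labels, "modal": modal})
        .sort_values(["cluster", "modal"])
        .index
    )
    return labels, list(order)
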