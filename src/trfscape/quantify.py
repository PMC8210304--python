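"""Read assignment and RPM expression matrices.

Reads are assigned to tRF candidates by exact sequence identity (the
zero-mismatch mapping regime reduces alignment to a hash lookup), counts
are normalized to reads per million mapped reads (RPM), and lowly
expressed candidates are removed per cohort with a quantile filter.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

from .annotation import TrfCandidate

logger = logging.getLogger(__name__)


class QuantificationError(ValueError):
    pass


def trim_adapter(seq: str, adapter: str, min_overlap: int = 3) -> str:
    """Trim a 3' adapter whose prefix matches the read's 3' tail exactly.

    The longest read suffix equal to a prefix of the adapter (>= min_overlap
    nt) is removed; reads without such a suffix are returned unchanged.
    """
    max_k = min(len(seq), len(adapter))
    for start in range(max(0, len(seq) - max_k), len(seq) - min_overlap + 1):
        if adapter.startswith(seq[start:]):
            return seq[:start]
    return seq


@dataclass
class ReadLibrary:
    """One sample's small-RNA reads as a sequence -> count table."""

    sample_id: str
    sequence_counts: dict[str, int]
    total_mapped_reads: int | None = None  # None: derive from assigned reads

    @classmethod
    def from_fastq(cls, path, sample_id: str, adapter: str | None = None,
                   total_mapped_reads: int | None = None) -> "ReadLibrary":
        from . import io as tio

        counts: Counter[str] = Counter()
        for seq in tio.iter_fastq_sequences(path):
            if adapter:
                seq = trim_adapter(seq, adapter)
            counts[seq] += 1
        return cls(sample_id, dict(counts), total_mapped_reads)

    @classmethod
    def from_sequences(cls, sequences, sample_id: str,
                       total_mapped_reads: int | None = None) -> "ReadLibrary":
        return cls(sample_id, dict(Counter(sequences)), total_mapped_reads)

    @property
    def n_reads(self) -> int:
        return int(sum(self.sequence_counts.values()))


def build_sequence_index(reference) -> dict[str, list[TrfCandidate]]:
    """Map candidate sequence -> candidates (>1 entry only across classes)."""
    index: dict[str, list[TrfCandidate]] = {}
    for cand in reference:
        index.setdefault(cand.sequence, []).append(cand)
    return index


def assign_reads(library: ReadLibrary, reference, sequence_index=None):
    """Count reads per candidate by exact sequence match (no mismatches).

    A read whose sequence equals candidates of *different* classes is
    counted once for each class and flagged in the QC dict; reads matching
    nothing are left unassigned.

    Returns (counts: pd.Series indexed by candidate name, qc: dict).
    """
    reference = list(reference)
    if not reference:
        raise QuantificationError("empty tRF reference")
    if sequence_index is None:
        sequence_index = build_sequence_index(reference)
    counts = pd.Series(0, index=[c.name for c in reference], dtype=np.int64)
    if not library.sequence_counts:
        logger.warning("library %s is empty; returning zero counts",
                       library.sample_id)
        return counts, {"assigned": 0, "total": 0, "ambiguous": 0,
                        "assignment_rate": 0.0, "ambiguity_rate": 0.0}
    assigned = ambiguous = 0
    for seq, n in library.sequence_counts.items():
        hits = sequence_index.get(seq)
        if not hits:
            continue
        assigned += n
        if len(hits) > 1:
            ambiguous += n
        for cand in hits:
            counts[cand.name] += n
    total = library.n_reads
    qc = {
        "assigned": int(assigned),
        "total": int(total),
        "ambiguous": int(ambiguous),
        "assignment_rate": assigned / total if total else 0.0,
        "ambiguity_rate": ambiguous / total if total else 0.0,
    }
    return counts, qc


def normalize_rpm(counts: pd.DataFrame, totals: pd.Series) -> pd.DataFrame:
    """RPM = counts / total_mapped_reads * 1e6, per sample (column)."""
    totals = totals.reindex(counts.columns)
    bad = totals.index[(totals.isna()) | (totals <= 0)]
    if len(bad):
        raise QuantificationError(
            f"non-positive or missing library total for sample(s) {list(bad)}"
        )
    return counts.div(totals, axis=1) * 1e6


@dataclass
class ExpressionMatrix:
    """tRF x sample counts with RPM normalization and sample/feature metadata.

    ``samples`` is indexed by sample id with at least ``cohort`` and
    ``condition`` ('tumor'/'normal') columns; survival and covariate columns
    ride along. ``features`` is indexed by tRF name with ``trf_class``,
    ``length`` and ``parents`` columns.
    """

    counts: pd.DataFrame
    totals: pd.Series
    samples: pd.DataFrame
    features: pd.DataFrame = None

    def __post_init__(self):
        if list(self.counts.columns) != list(self.totals.index):
            self.totals = self.totals.reindex(self.counts.columns)
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise QuantificationError(f"samples without metadata: {sorted(missing)[:5]}")
        self.samples = self.samples.loc[self.counts.columns]
        if self.features is not None:
            self.features = self.features.reindex(self.counts.index)
        if (self.counts.values < 0).any():
            raise QuantificationError("negative counts")

    @cached_property
    def rpm(self) -> pd.DataFrame:
        return normalize_rpm(self.counts, self.totals)

    @property
    def cohorts(self) -> list[str]:
        return sorted(self.samples["cohort"].unique())

    def subset(self, trfs=None, samples=None, cohort=None,
               trf_class=None) -> "ExpressionMatrix":
        counts = self.counts
        feats = self.features
        if trf_class is not None and feats is not None:
            trfs_cls = feats.index[feats["trf_class"] == trf_class]
            counts = counts.loc[counts.index.intersection(trfs_cls)]
        if trfs is not None:
            counts = counts.loc[[t for t in trfs if t in counts.index]]
        cols = counts.columns
        if cohort is not None:
            cols = [s for s in cols if self.samples.at[s, "cohort"] == cohort]
        if samples is not None:
            cols = [s for s in cols if s in set(samples)]
        counts = counts[cols]
        return ExpressionMatrix(
            counts=counts,
            totals=self.totals.loc[cols],
            samples=self.samples.loc[cols],
            features=None if feats is None else feats.reindex(counts.index),
        )

    def condition_mask(self, condition: str) -> pd.Index:
        return self.samples.index[self.samples["condition"] == condition]


def quantify_cohorts(libraries, reference, samples: pd.DataFrame) -> ExpressionMatrix:
    """Assign every library against the reference and assemble the matrix.

    ``total_mapped_reads`` defaults to the number of reads assigned to any
    candidate when a library does not carry an externally supplied total.
    """
    reference = list(reference)
    index = build_sequence_index(reference)
    cols, totals, qcs = {}, {}, {}
    for lib in libraries:
        counts, qc = assign_reads(lib, reference, index)
        cols[lib.sample_id] = counts
        totals[lib.sample_id] = (
            lib.total_mapped_reads
            if lib.total_mapped_reads is not None
            else max(qc["assigned"], 1)
        )
        qcs[lib.sample_id] = qc
    counts_df = pd.DataFrame(cols)
    features = pd.DataFrame(
        {
            "trf_class": [c.trf_class for c in reference],
            "length": [c.length for c in reference],
            "parents": [";".join(sorted(c.parent_families)) for c in reference],
        },
        index=[c.name for c in reference],
    )
    mat = ExpressionMatrix(
        counts=counts_df,
        totals=pd.Series(totals),
        samples=samples.loc[counts_df.columns],
        features=features,
    )
    mat.qc = qcs
    return mat


def filter_expressed(
    matrix: ExpressionMatrix, quantile: float = 0.9, threshold: float = 1.0
):
    """Per-cohort robust-expression filter on RPM.

    A tRF is retained in a cohort iff the ``quantile`` (linear-interpolation
    estimator) of its RPM across that cohort's samples is >= ``threshold``
    (default: 90th-quantile RPM >= 1). Returns ``(membership, filtered)``
    where membership is a tRF x cohort boolean frame and ``filtered``
    restricts the matrix to the union of retained sets.
    """
    if not 0 < quantile < 1:
        raise QuantificationError("quantile must lie in (0, 1)")
    rpm = matrix.rpm
    membership = {}
    for cohort in matrix.cohorts:
        cols = matrix.samples.index[matrix.samples["cohort"] == cohort]
        if len(cols) < 2:
            logger.warning("cohort %s has <2 samples; skipped by filter", cohort)
            continue
        q = np.quantile(rpm[cols].values, quantile, axis=1)
        # float guard so exact boundary values (e.g. interpolated 1.0) retain
        membership[cohort] = pd.Series(q >= threshold - 1e-9, index=rpm.index)
    if not membership:
        raise QuantificationError("no cohort with >=2 samples to filter")
    member_df = pd.DataFrame(membership)
    keep = member_df.any(axis=1)
    filtered = matrix.subset(trfs=member_df.index[keep])
    return member_df, filtered


def compartment_enrichment(cyto: ExpressionMatrix, nuc: ExpressionMatrix,
                           eps: float = 0.01):
    """Cytoplasm-vs-nucleus enrichment of tRF expression.

    Returns ``(class_ratios, per_trf_log2)``: per tRF class the ratio of
    summed mean RPM (cytoplasm / nucleus) and per tRF
    log2((cyto RPM + eps) / (nuc RPM + eps)) on mean RPM across replicates.
    """
    shared = cyto.rpm.index.intersection(nuc.rpm.index)
    if shared.empty:
        raise QuantificationError("no shared tRFs between compartments")
    c = cyto.rpm.loc[shared].mean(axis=1)
    n = nuc.rpm.loc[shared].mean(axis=1)
    per_trf = np.log2((c + eps) / (n + eps))
    per_trf.name = "log2_cyto_over_nuc"
    classes = cyto.features.loc[shared, "trf_class"]
    class_ratios = c.groupby(classes).sum() / n.groupby(classes).sum().replace(0, np.nan)
    class_ratios.name = "cyto_over_nuc"
    return class_ratios, per_trf
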