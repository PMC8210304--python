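"""Synthetic smRNA-seq study generator with full ground-truth bookkeeping.

Emulates multi-cohort tumor/normal small-RNA libraries in which every
pipeline-recoverable structure is planted explicitly:

* a tRNA gene reference (GtRNAdb-style FASTA, mitochondrial and ``tRX-``
  naming paths included),
* fragment size distributions with the three canonical cleavage peaks per
  end (5': 18-20, 23 and 30 nt; 3': 16-18, 22 and 24-25 nt),
* tumor-vs-normal fold changes on chosen tRFs,
* expression subtypes that reweight fragment size classes,
* driver tRFs whose expression tilts an exponential survival hazard.

Counts follow a negative-binomial (gamma-Poisson) model over expected
library fractions; ``dispersion=0`` degenerates to deterministic rounded
expectations so that quantification round-trips are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import (
    FIVE_PRIME,
    THREE_PRIME,
    THREE_PRIME_U,
    TrnaGene,
    enumerate_trf_candidates,
)
from .quantify import ExpressionMatrix, ReadLibrary

# fragment-size classes used by the subtype machinery (3'-tRF analogues of
# the 18 nt / 22 nt / 24 nt signature groups)
SIZE_CLASS_BINS: dict[str, tuple[int, int]] = {
    "18nt": (15, 18),
    "22nt": (19, 23),
    "24nt": (24, 30),
}

_ISOACCEPTORS = [
    ("Ile", "AAT"), ("Lys", "CTT"), ("Arg", "ACG"), ("Gly", "GCC"),
    ("Glu", "CTC"), ("Asp", "GTC"), ("Val", "CAC"), ("Ala", "AGC"),
    ("Thr", "AGT"), ("Ser", "GCT"), ("Leu", "CAG"), ("Phe", "GAA"),
    ("His", "GTG"), ("Gln", "CTG"), ("Asn", "GTT"),
]


def size_class_of(length: int) -> str:
    for name, (lo, hi) in SIZE_CLASS_BINS.items():
        if lo <= length <= hi:
            return name
    raise ValueError(f"length {length} outside the configured size classes")


@dataclass
class PlantedDriver:
    """An oncogenic tRF: fold-change up in tumors of ``cohorts`` and an
    exponential-hazard multiplier of ``hazard_ratio`` per SD of its
    (log) expression in those cohorts."""

    fold: float = 4.0
    hazard_ratio: float = 2.0
    cohorts: tuple = ()
    trf: str | None = None  # filled in at build time when None


@dataclass
class SimulationConfig:
    """Study conditions for the generator (defaults are the conditions the
    rest of the package is exercised under)."""

    seed: int = 0
    n_cohorts: int = 6
    n_tumor: int = 30
    n_normal: int = 20
    n_trna_genes: int = 30
    trailer_window: int = 50
    length_range: tuple = (15, 30)
    five_prime_peaks: dict = field(
        default_factory=lambda: {18: 0.18, 19: 0.18, 20: 0.18, 23: 0.12, 30: 0.09}
    )
    three_prime_peaks: dict = field(
        default_factory=lambda: {16: 0.14, 17: 0.14, 18: 0.14, 22: 0.30,
                                 24: 0.10, 25: 0.10}
    )
    end_shares: dict = field(
        default_factory=lambda: {FIVE_PRIME: 0.50, THREE_PRIME: 0.45,
                                 THREE_PRIME_U: 0.05}
    )
    library_size: int = 100_000
    dispersion: float = 0.3
    gene_abundance_sigma: float = 1.0
    cohort_jitter_sigma: float = 0.3
    # planted tumor-vs-normal fold changes
    n_de_trfs: int = 0
    de_fold: float = 4.0
    de_cohorts: tuple | None = None  # None = every cohort
    # planted expression subtypes (0 = none)
    subtype_k: int = 0
    subtype_end: str = THREE_PRIME
    subtype_boost: float = 5.0
    # planted drivers
    drivers: tuple = ()
    # survival model
    baseline_hazard: float = 1.0 / 1000.0  # per day
    censoring_ratio: float = 2.0 / 3.0  # censor rate / baseline hazard (~60% events)

    def cohort_names(self) -> list[str]:
        return [f"C{i + 1:02d}" for i in range(self.n_cohorts)]


def _random_seq(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def simulate_reference(
    n_genes: int = 30,
    seed: int = 0,
    trailer_window: int = 50,
    duplicate_prefix_pair: bool = False,
    include_genomic_cca: bool = True,
    rng=None,
):
    """Generate tRNA-like genes plus the FASTA records encoding them.

    Genes are 70-90 nt (pre-CCA) with GtRNAdb-style headers; the set always
    contains at least one mitochondrial gene and one ``tRX-`` gene so the
    full naming scheme is exercised. Trailers are 50 nt with an embedded
    poly-U (T) tract so 3'U-tRF candidates exist.

    Returns ``(genes, records)`` where records are (header, gene_sequence)
    pairs ready to be written as FASTA.
    """
    if n_genes < 3:
        raise ValueError("need at least 3 tRNA genes")
    if rng is None:
        rng = np.random.default_rng(seed)
    genes, records = [], []
    per_iso_counter: dict[str, int] = {}
    for i in range(n_genes):
        if i == 1:
            family = f"tRX-{int(rng.integers(1, 999_999)):06d}"
            isotype, anticodon = "Und", _random_seq(rng, 3)
            header_extra = f" {isotype} {anticodon}"
        else:
            isotype, anticodon = _ISOACCEPTORS[i % len(_ISOACCEPTORS)]
            per_iso_counter[isotype] = per_iso_counter.get(isotype, 0) + 1
            family = f"{isotype}{anticodon}-{per_iso_counter[isotype]}-1"
            header_extra = ""
        mito = i == 2
        gene_len = int(rng.integers(70, 91))
        seq = _random_seq(rng, gene_len)
        genomic_cca = include_genomic_cca and i == 3
        if genomic_cca:
            seq = seq[:-3] + "CCA"
        if duplicate_prefix_pair and i == 4:
            seq = records[0][1][:25] + seq[25:]
        trailer = (
            _random_seq(rng, 17) + "TTTT" + _random_seq(rng, trailer_window - 21)
        )
        header = family + header_extra
        if mito:
            header += " MT"
        header += f" trailer={trailer}"
        if genomic_cca:
            header += " cca=genomic"
        # CCA already genomically encoded is not doubled
        mature = seq if genomic_cca else seq + "CCA"
        genes.append(
            TrnaGene(
                family_name=family,
                isotype=isotype,
                anticodon=anticodon,
                is_mitochondrial=mito,
                gene_sequence=seq,
                mature_sequence=mature,
                trailer_sequence=trailer[:trailer_window],
            )
        )
        records.append((header, seq))
    return genes, records


def _size_probs(peaks: dict, length_range) -> dict[int, float]:
    """Peak masses plus the remaining mass spread uniformly over the other
    sizes of the range."""
    lo, hi = length_range
    sizes = range(lo, hi + 1)
    peak_mass = sum(peaks.values())
    if peak_mass > 1.0 + 1e-9:
        raise ValueError("peak masses exceed 1")
    others = [s for s in sizes if s not in peaks]
    rest = (1.0 - peak_mass) / len(others) if others else 0.0
    return {s: peaks.get(s, rest) for s in sizes}


@dataclass
class GroundTruth:
    """Everything that was planted, keyed the same way the pipeline reports."""

    counts: pd.DataFrame  # candidate x sample (after cross-class duplication)
    samples: pd.DataFrame  # cohort, condition, subtype, os_time, os_event, ...
    totals: pd.Series  # true mapped-read totals per sample
    de_table: pd.DataFrame  # trf, cohort, fold
    drivers: list[PlantedDriver]
    size_probs: dict  # end -> {size: prob} baseline distribution
    subtype_archetype: dict  # subtype label -> boosted size class


class SimulatedStudy:
    """A fully realized synthetic study: reference, libraries and truth."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.genes, self.records = simulate_reference(
            config.n_trna_genes,
            trailer_window=config.trailer_window,
            rng=rng,
        )
        self.candidates = enumerate_trf_candidates(self.genes, config.length_range)
        self._build(rng)

    # -- generative model -------------------------------------------------
    def _build(self, rng) -> None:
        cfg = self.config
        cands = self.candidates
        cand_names = [c.name for c in cands]
        name_to_idx = {n: i for i, n in enumerate(cand_names)}

        # generation units: (gene, end, size) cells contributing to candidates
        size_probs = {
            FIVE_PRIME: _size_probs(cfg.five_prime_peaks, cfg.length_range),
            THREE_PRIME: _size_probs(cfg.three_prime_peaks, cfg.length_range),
        }
        fam_of = {g.family_name: g for g in self.genes}
        base_abund = {
            g.family_name: float(rng.lognormal(0.0, cfg.gene_abundance_sigma))
            for g in self.genes
        }
        units = []  # (cand_idx, family, end, size, weight)
        for ci, cand in enumerate(cands):
            for fam in cand.parent_families:
                gene = fam_of[fam]
                if cand.trf_class == THREE_PRIME_U:
                    n_valid = sum(
                        1 for c in cands
                        if c.trf_class == THREE_PRIME_U and fam in c.parent_families
                    )
                    w = (
                        base_abund[fam]
                        * cfg.end_shares[THREE_PRIME_U]
                        / max(n_valid, 1)
                    )
                else:
                    w = (
                        base_abund[fam]
                        * cfg.end_shares[cand.trf_class]
                        * size_probs[cand.trf_class][cand.length]
                    )
                units.append((ci, fam, cand.trf_class, cand.length, w))
        unit_cand = np.array([u[0] for u in units])
        unit_end = np.array([u[2] for u in units])
        unit_size = np.array([u[3] for u in units])
        unit_w_base = np.array([u[4] for u in units], dtype=float)

        # choose planted DE / driver candidates among well-expressed,
        # unambiguous mature-end fragments
        cand_base = np.bincount(unit_cand, weights=unit_w_base, minlength=len(cands))
        seq_counts: dict[str, int] = {}
        for c in cands:
            seq_counts[c.sequence] = seq_counts.get(c.sequence, 0) + 1
        eligible = [
            i for i, c in enumerate(cands)
            if c.trf_class != THREE_PRIME_U
            and seq_counts[c.sequence] == 1
            and cand_base[i] >= np.median(cand_base[cand_base > 0])
        ]
        rng.shuffle(eligible)
        cohorts = cfg.cohort_names()
        de_rows = []
        de_cohorts = list(cfg.de_cohorts) if cfg.de_cohorts is not None else cohorts
        pick = 0
        for _ in range(cfg.n_de_trfs):
            trf = cand_names[eligible[pick]]
            pick += 1
            for ch in de_cohorts:
                de_rows.append({"trf": trf, "cohort": ch, "fold": cfg.de_fold})
        drivers = []
        for drv in cfg.drivers:
            drv = replace(drv)
            if drv.trf is None:
                drv.trf = cand_names[eligible[pick]]
                pick += 1
            if not drv.cohorts:
                drv.cohorts = tuple(cohorts[: max(1, cfg.n_cohorts // 2)])
            drivers.append(drv)
            for ch in drv.cohorts:
                de_rows.append({"trf": drv.trf, "cohort": ch, "fold": drv.fold})
        de_table = pd.DataFrame(de_rows, columns=["trf", "cohort", "fold"])
        fold_by_cohort: dict[str, np.ndarray] = {}
        for ch in cohorts:
            fold = np.ones(len(cands))
            for _, row in de_table[de_table["cohort"] == ch].iterrows():
                fold[name_to_idx[row["trf"]]] *= row["fold"]
            fold_by_cohort[ch] = fold

        # subtype archetypes: archetype r boosts one size class at one end
        classes = list(SIZE_CLASS_BINS)
        archetype_of = {
            s + 1: classes[s % len(classes)] for s in range(cfg.subtype_k)
        }
        unit_class = np.array([size_class_of(s) for s in unit_size])

        sample_rows = []
        count_cols: dict[str, np.ndarray] = {}
        seq_count_cols: dict[str, dict[str, int]] = {}
        for ch in cohorts:
            jitter = rng.lognormal(0.0, cfg.cohort_jitter_sigma, size=len(self.genes))
            jitter_by_fam = dict(zip((g.family_name for g in self.genes), jitter))
            w_cohort = unit_w_base * np.array([jitter_by_fam[u[1]] for u in units])
            # planted subtype mixing realized exactly (balanced allocation,
            # randomly permuted) so cohort-level proportions are by design
            if cfg.subtype_k:
                base = np.resize(
                    np.arange(1, cfg.subtype_k + 1), cfg.n_tumor
                )
                subtype_of = rng.permutation(base)
            for cond, n in (("tumor", cfg.n_tumor), ("normal", cfg.n_normal)):
                for j in range(n):
                    sid = f"{ch}_{'T' if cond == 'tumor' else 'N'}{j + 1:03d}"
                    w = w_cohort.copy()
                    subtype = np.nan
                    if cond == "tumor":
                        w = w * fold_by_cohort[ch][unit_cand]
                        if cfg.subtype_k:
                            subtype = int(subtype_of[j])
                            boost_mask = (unit_end == cfg.subtype_end) & (
                                unit_class == archetype_of[subtype]
                            )
                            w = np.where(boost_mask, w * cfg.subtype_boost, w)
                    frac = w / w.sum()
                    mu = cfg.library_size * frac
                    if cfg.dispersion == 0:
                        unit_counts = np.round(mu).astype(np.int64)
                    else:
                        lam = rng.gamma(
                            shape=1.0 / cfg.dispersion,
                            scale=mu * cfg.dispersion,
                        )
                        unit_counts = rng.poisson(lam).astype(np.int64)
                    cand_counts = np.bincount(
                        unit_cand, weights=unit_counts, minlength=len(cands)
                    ).astype(np.int64)
                    count_cols[sid] = cand_counts
                    seqs: dict[str, int] = {}
                    for c, n_reads in zip(cands, cand_counts):
                        if n_reads:
                            seqs[c.sequence] = seqs.get(c.sequence, 0) + int(n_reads)
                    seq_count_cols[sid] = seqs
                    sample_rows.append(
                        {
                            "sample_id": sid,
                            "cohort": ch,
                            "condition": cond,
                            "subtype": subtype,
                            "platform": "sim",
                        }
                    )

        counts = pd.DataFrame(count_cols, index=cand_names)
        # reads whose sequence matches candidates of several classes are
        # counted once per class downstream; mirror that in the truth
        dup_groups: dict[str, list[str]] = {}
        for c in cands:
            dup_groups.setdefault(c.sequence, []).append(c.name)
        for names in dup_groups.values():
            if len(names) > 1:
                counts.loc[names] = counts.loc[names].sum(axis=0).values[None, :]
        totals = pd.Series(
            {sid: sum(d.values()) for sid, d in seq_count_cols.items()}
        )
        samples = pd.DataFrame(sample_rows).set_index("sample_id")

        # survival: exponential hazard tilted by realized driver expression
        rpm = counts.div(totals, axis=1) * 1e6
        h = pd.Series(cfg.baseline_hazard, index=samples.index, dtype=float)
        for drv in drivers:
            expr = np.log2(rpm.loc[drv.trf] + 1.0)
            for ch in drv.cohorts:
                mask = (samples["cohort"] == ch) & (samples["condition"] == "tumor")
                z = expr[mask.values]
                sd = z.std(ddof=0)
                z = (z - z.mean()) / (sd if sd > 0 else 1.0)
                h.loc[z.index] *= drv.hazard_ratio ** z
        t_event = rng.exponential(1.0 / h.values)
        censor_rate = cfg.baseline_hazard * cfg.censoring_ratio
        t_censor = rng.exponential(1.0 / censor_rate, size=len(h))
        samples["os_time"] = np.minimum(t_event, t_censor)
        samples["os_event"] = (t_event <= t_censor).astype(int)
        samples["stage"] = rng.integers(1, 5, size=len(samples))
        samples["ssign"] = np.round(rng.uniform(0, 10, size=len(samples)), 1)

        self._seq_counts = seq_count_cols
        self.truth = GroundTruth(
            counts=counts,
            samples=samples,
            totals=totals,
            de_table=de_table,
            drivers=drivers,
            size_probs={
                FIVE_PRIME: _size_probs(cfg.five_prime_peaks, cfg.length_range),
                THREE_PRIME: _size_probs(cfg.three_prime_peaks, cfg.length_range),
            },
            subtype_archetype=archetype_of,
        )

    # -- materialization ---------------------------------------------------
    def libraries(self) -> list[ReadLibrary]:
        """Per-sample read libraries (sequence -> count tables)."""
        return [
            ReadLibrary(sid, dict(seqs))
            for sid, seqs in self._seq_counts.items()
        ]

    def expression_matrix(self) -> ExpressionMatrix:
        """ExpressionMatrix assembled directly from the ground-truth counts."""
        feats = pd.DataFrame(
            {
                "trf_class": [c.trf_class for c in self.candidates],
                "length": [c.length for c in self.candidates],
                "parents": [";".join(sorted(c.parent_families)) for c in self.candidates],
            },
            index=[c.name for c in self.candidates],
        )
        return ExpressionMatrix(
            counts=self.truth.counts.copy(),
            totals=self.truth.totals.copy(),
            samples=self.truth.samples.copy(),
            features=feats,
        )

    def write_reference_fasta(self, path) -> None:
        from . import io as tio

        tio.write_fasta(self.records, path)

    def write_fastq_dir(self, out_dir) -> pd.DataFrame:
        """Write one FASTQ per sample plus a metadata TSV; returns metadata."""
        import os

        from . import io as tio

        os.makedirs(out_dir, exist_ok=True)
        rng = np.random.default_rng(self.config.seed + 7)
        for sid, seqs in self._seq_counts.items():
            reads = np.repeat(
                np.array(list(seqs.keys()), dtype=object),
                np.array(list(seqs.values()), dtype=int),
            )
            rng.shuffle(reads)
            tio.write_fastq(reads, os.path.join(out_dir, f"{sid}.fastq"))
        meta = self.truth.samples.reset_index()
        meta.to_csv(os.path.join(out_dir, "metadata.tsv"), sep="\t", index=False)
        return meta


def simulate_study(config: SimulationConfig | None = None, **kwargs) -> SimulatedStudy:
    """Convenience constructor: ``simulate_study(seed=1, n_cohorts=2, ...)``."""
    if config is None:
        config = SimulationConfig(**kwargs)
    return SimulatedStudy(config)


def simulate_survival(
    n: int = 250,
    hazard_ratio: float = 2.0,
    seed: int = 0,
    baseline_hazard: float = 1.0 / 1000.0,
    censoring_ratio: float = 2.0 / 3.0,
) -> pd.DataFrame:
    """Standalone survival cohort: exponential hazard h0 * HR**z with
    standard-normal covariate z and independent exponential censoring
    (defaults give ~60% observed events)."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    h = baseline_hazard * hazard_ratio ** z
    t_event = rng.exponential(1.0 / h)
    t_censor = rng.exponential(1.0 / (baseline_hazard * censoring_ratio), size=n)
    return pd.DataFrame(
        {
            "z": z,
            "os_time": np.minimum(t_event, t_censor),
            "os_event": (t_event <= t_censor).astype(int),
        },
        index=[f"S{i + 1:04d}" for i in range(n)],
    )


def emit_expression_resources(
    study: SimulatedStudy,
    n_genes: int = 300,
    module_size: int = 30,
    rho: float = 0.6,
    n_signatures: int = 12,
    seed: int | None = None,
):
    """Companion resources: a gene-expression matrix with modules correlated
    to the first planted driver (or a well-expressed tRF when no driver was
    planted), a toy GMT signature catalogue and a signature -> program map.

    Returns ``(gene_expr, gmt, program_map)`` where gene_expr is genes x
    tumor-sample, gmt maps signature name -> gene list and program_map is a
    Series signature -> program.
    """
    cfg = study.config
    rng = np.random.default_rng(cfg.seed + 13 if seed is None else seed)
    samples = study.truth.samples
    tumors = samples.index[samples["condition"] == "tumor"]
    rpm = study.truth.counts.div(study.truth.totals, axis=1) * 1e6
    if study.truth.drivers:
        anchor = study.truth.drivers[0].trf
    else:
        anchor = rpm.mean(axis=1).idxmax()
    expr = np.log2(rpm.loc[anchor, tumors] + 1.0)
    # standardize within cohort so the module tracks the tRF in every cohort
    z = expr.groupby(samples.loc[tumors, "cohort"]).transform(
        lambda v: (v - v.mean()) / (v.std(ddof=0) or 1.0)
    )
    gene_names = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    data = rng.standard_normal((n_genes, len(tumors)))
    data[:module_size] = (
        rho * z.values[None, :]
        + np.sqrt(1.0 - rho**2) * data[:module_size]
    )
    gene_expr = pd.DataFrame(data, index=gene_names, columns=tumors)
    module_genes = gene_names[:module_size]
    gmt = {"MODULE_DRIVER": list(module_genes)}
    programs = {}
    programs["MODULE_DRIVER"] = "GP_driver_module"
    for i in range(n_signatures - 1):
        pool = gene_names[module_size:]
        size = min(int(rng.integers(15, 40)), len(pool))
        gmt[f"RANDOM_SET_{i + 1:02d}"] = list(
            rng.choice(pool, size=size, replace=False)
        )
        programs[f"RANDOM_SET_{i + 1:02d}"] = f"GP_random_{i % 3 + 1}"
    program_map = pd.Series(programs, name="program")
    return gene_expr, gmt, program_map
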