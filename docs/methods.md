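# Methods

This note documents the models, parameter choices and numerical
conventions behind `trfscape`, what the synthetic-data generator does and
does not emulate, and the known limitations.

## tRF reference model

A tRNA gene record carries its genomic sequence, optional intron
intervals (header `introns=` field, 1-based inclusive, or a BED companion
file, 0-based half-open) and an optional 3′ trailer. The mature form is
the spliced sequence with `CCA` appended; when the annotation flags a
genomically encoded CCA (`cca=genomic`) and the spliced sequence already
ends in CCA, nothing is appended — CCA is never doubled. Mature lengths
outside 60–100 nt are rejected as malformed. Trailers are truncated to a
configurable window (default 50 nt downstream of the gene 3′ end, the
scale at which pol-III termination occurs); genes without trailer
annotation simply produce no 3′U candidates.

Candidates are enumerated per gene and length L in [15, 30] (configurable
within [10, 35]):

* 5′-tRF: mature prefix of length L (cleavage after mature base L);
* 3′-tRF: mature suffix of length L (always ends in CCA; positions are
  counted backwards from the last CCA base);
* 3′U-tRF: first L trailer nucleotides, kept only when ending in ≥ 2
  consecutive T (the RNA poly-U terminator tract; the motif is a
  parameter).

Internal fragments and halves (> 30 nt) are excluded by construction.
Candidates with identical (class, sequence) are merged at build time and
the parent-family set unioned, so each read has at most one candidate per
class and counting is unambiguous; the lexicographically smallest family
names the merged fragment (`<5'|3'|3'U>-[M-]<family>-L<length>`, `M-` for
mitochondrial genes). Enumeration is order-independent: outputs are
canonically sorted.

## Quantification

Reads are assigned by exact sequence identity (a hash lookup): the
zero-mismatch mapping regime makes an aligner unnecessary, and a single
substitution voids the match. A read whose sequence equals candidates of
*different* classes is counted once per class and surfaced in the QC
ambiguity rate. Expression is RPM = count / total-mapped × 10⁶; the
per-sample total defaults to the number of reads assigned to the
reference when no external total (e.g. from an upstream BAM) is supplied
— whether totals should count all genome-mapped reads is exposed via
`ReadLibrary.total_mapped_reads`.

The robust-expression filter retains a tRF in a cohort when the
90th-quantile (linear interpolation between order statistics, the
`numpy` default, chosen so the filter is bit-reproducible) of its RPM
across that cohort's samples is ≥ 1 RPM; a 1e-9 absolute guard keeps
exact boundary values (e.g. an interpolated quantile of exactly 1.0) on
the retained side of float round-off. Cohorts with fewer than two
samples are skipped with a warning. Adapter trimming removes the longest
read suffix equal to an adapter prefix, requiring ≥ 3 nt overlap.
Compartment enrichment uses log2((cyto RPM + ε)/(nuc RPM + ε)) with
ε = 0.01 RPM.

## Jensen–Shannon cleavage score

Cleavage patterns are probability distributions over fragment sizes or
positions (vectors summing to 1 within 1e-8; true zeros allowed,
0·log 0 := 0; no pseudocounts). Entropy is base 2, which is what makes
the pairwise score

    JS(e¹, e²) = H((e¹+e²)/2) − (H(e¹)+H(e²))/2

range over [0, 1]: 0 iff the two distributions are identical, 1 iff their
supports are disjoint. For n ≥ 2 distributions the default score is the
generalized JS, H(mean) − mean(H), normalized by log₂ n so the [0, 1]
range and both endpoints are preserved and the n = 2 case reduces
exactly to the pairwise form. A `method="cabili"` switch returns the JS
*distance* analogue √(generalized JS) — same endpoints, metric-like
scale — for users who prefer distance-flavoured specificity scores; the
choice between the two is a genuine design freedom and the generalized
form is the default because of its exact n = 2 limit.

Size profiles average, across a group's samples, each sample's
normalized RPM-by-size vector (samples with zero class mass are
skipped). Position landscapes distribute each tRNA family's mean-RPM
mass over fragment sizes at one end; mass from merged multi-family
candidates is attributed to the naming family. The per-tRNA
concentration score is JS(observed, uniform); families above a 0.5
threshold (configurable) are called cleavage hotspots. Pattern
clustering is k-means on the probability vectors (default k = 4, 25
restarts, fixed seed); rows are canonically sorted before fitting so the
result is invariant to input order, clusters are relabelled by ascending
mean modal position, and the display order groups families by cluster
then modal position.

## Differential expression

Per tRF, a two-sided Mann–Whitney test of tumor vs normal RPM. The
p-value uses exact enumeration when both groups have ≤ 25 samples and
the pooled row is tie-free, otherwise the normal approximation with tie
correction — the cutoff includes the 20 v 20 case where the exact tail
is still cheap, and ties (common with zero counts) force the asymptotic
branch anyway. BH correction is applied within (cohort × tRF class) to
match per-cohort, per-class reporting. Fold change is
(tumor median + ε)/(normal median + ε) with ε = 0.01 RPM — medians
because RPM is heavily skewed. Calls: up iff FDR < 0.01 and FC > 2;
down iff FDR < 0.01 and FC < 0.5. Cohorts need more than 15 normal
samples (min_normals = 16) to be tested; smaller cohorts are skipped
with a log entry. The global shift test is a two-sided t-test on
per-sample total class RPM. Note RPM is compositional: planting
upregulation on a few fragments necessarily dilutes the rest, so global
shifts and individual calls can point in opposite directions.

## Subtyping

NMF input is log2(RPM+1) with per-tRF minimum subtraction (keeps
non-negativity without distorting between-sample contrasts); constant
rows are dropped. Factorization is scikit-learn NMF with multiplicative
updates under KL divergence (the Brunet-style recipe), random init,
max 2000 iterations, tol 1e-6. For each candidate rank k in 2–6, 50
random restarts (default) yield a consensus matrix of co-assignment
frequencies (assignment = argmax factor loading); average-linkage
clustering of 1 − consensus gives a cophenetic correlation per k. The
chosen k maximizes the cophenetic correlation; when several k are
perfectly stable (ties within 1e-6, e.g. a clean 3-group structure is
also perfectly 2-separable) the largest such k wins, since a coarser cut
of a perfectly stable finer structure is always equally stable. Samples
are canonically sorted first, so results do not depend on input order;
labels are 1..k by first appearance.

Signatures: per tRF, the t-statistic of its log2 expression in each
subtype vs the rest; a tRF joins its best subtype when t ≥ 3 and its BH
FDR (across tRFs) < 0.05; subtypes with < 3 samples are suppressed.
Projection standardizes the validation matrix per tRF and assigns each
sample to the subtype with the most correlated signature centroid
(discovery-set standardized means); < 80% signature coverage warns, zero
coverage errors.

Survival: Kaplan–Meier curves per group, multi-group log-rank p, and a
Cox proportional-hazards model with subtype indicator contrasts against
a reference group, optionally adjusted for clinical covariates (stage,
SSIGN score — always consumed as a precomputed column, never computed).
Degenerate fits (e.g. an all-censored group) report missing hazard
ratios with a log entry rather than failing the analysis. For
continuous expression (driver screen) groups come from a cohort median
split.

## Pan-cancer analysis

The activity matrix holds, per tRF and per (cohort, subtype), the
t-score of that tRF in the subtype vs the cohort's other samples,
computed on per-cohort standardized log2(RPM+1) (standardization chosen
so cross-cohort columns are comparable). Features must be present in at
least `min_cohorts` cohorts (default: all but two, mirroring a
13-of-15-style presence rule); absent features contribute a neutral 0.
Superclusters are average-linkage hierarchical clusters of the columns
under correlation distance (1 − Pearson), with columns canonically
sorted first so the partition is order-invariant. Each supercluster is
summarized by the fragment-size-class composition of its members'
signature tRFs (t > 2), with classes ≤ 18 nt, 19–23 nt and ≥ 24 nt —
the 18 nt / 22 nt / 24 nt signature groups.

ssGSEA follows the rank-weighted ECDF-difference construction: per
sample, genes are ranked by expression, in-set genes weighted by
rank^0.25, and the score is the summed difference between the weighted
in-set ECDF and the unweighted out-set ECDF. Because weights grow with
rank, the raw running sum is positively offset even for random sets; by
default the sample's expected baseline (the same running sum with every
gene treated as a fractional set member) is subtracted, which centers
random sets at ~0 while leaving determinism, the extremal top-set
property and invariance to monotone transforms untouched (`center=False`
restores the raw sum; set-size normalization is also switchable).
Program-level characterization ranks signatures within a supercluster by
the 25th quantile of their subtype t-scores (descending) and calls the
majority program among the top 50; ties are reported as no-call.

## Driver screen

Fisher's combined probability: X² = −2 Σ ln pᵢ against χ² with 2k df. A
cohort qualifies for a tRF when the tRF is called up there AND its
median-split high-expression group has worse survival (log-rank p < 0.05
with a positive Cox coefficient for the high indicator). tRFs with ≥ 2
qualifying cohorts combine those cohorts' DE and survival p-values into
P_comb; drivers are called by BH at 0.05 computed across *all* tested
tRFs with non-candidates carrying p = 1 — with the number of tests
fixed, lowering p-values can only enlarge the BH rejection set, so
relaxing the cohort floor can never un-call a driver. Caveat: DE and
survival p-values from the same cohort are correlated, so Fisher's
independence assumption is optimistic; the direction gates are the
mitigation, and P_comb should be read as a ranking score more than a
calibrated tail probability.

Tissue specificity is JS(mean-RPM-across-cohorts distribution, uniform)
— 0 for even expression, larger for cohort-restricted expression;
invariant to cohort order and rescaling. Co-expression uses per-cohort
Spearman correlation (t approximation for p), BH across genes within
cohort, and reports genes significant (FDR < 0.05, |ρ| ≥ 0.3) with a
consistent sign in ≥ 8 cohorts; cohorts with < 10 shared samples are
skipped.

## Synthetic-data generator

The generator is the package's study-conditions oracle. Reference:
random tRNA-like genes of 70–90 nt (pre-CCA) with GtRNAdb-style headers,
always including a mitochondrial and a `tRX-` gene (naming-path
coverage) and 50 nt trailers with an embedded TTTT tract (3′U coverage);
an optional duplicated-prefix gene pair exercises candidate merging.

Expression: per gene a lognormal abundance (σ = 1) with per-cohort
lognormal jitter (σ = 0.3); end shares 0.50/0.45/0.05 for 5′/3′/3′U;
fragment sizes drawn from the planted peak distributions — 5′ peaks
{18: .18, 19: .18, 20: .18, 23: .12, 30: .09} (three-peak mass 0.75) and
3′ peaks {16: .14, 17: .14, 18: .14, 22: .30, 24: .10, 25: .10} (mass
0.92), remainder uniform over the other sizes in 15–30 — matching the
canonical 18–20/23/30 nt and 16–18/22/24–25 nt size preferences and
their reported abundance shares. Planted fold changes multiply the
target fragments' expected fractions in tumor samples of chosen cohorts;
subtype archetypes boost one size class at one end by 5× (subtype
heatmaps in this field show strong block structure); mixing proportions
are realized exactly by balanced allocation with a random permutation.
Expected fractions are renormalized per sample (sequencing is
compositional), scaled to the library size (default 1e5 reads/sample)
and drawn as negative-binomial counts via gamma–Poisson mixing with
dispersion 0.3; dispersion 0 degenerates to deterministic rounded
expectations so quantification round trips are exact. Reads whose
sequence collides across classes are duplicated in the ground-truth
counts exactly as the quantifier counts them.

Survival: exponential event times with hazard h₀·HRᶻ (h₀ = 1/1000 per
day), z the realized standardized log2 RPM of each planted driver within
its active cohorts, and independent exponential censoring at
h₀·(2/3), giving ~60% observed events. Companion resources: a gene
expression matrix whose first module tracks the driver's within-cohort
standardized expression at a target correlation (default 0.6), plus a
toy GMT catalogue and signature→program map.

What the generator does **not** emulate: sequencing errors, adapter
contamination, tRNA-modification-induced truncation or mis-incorporation
(the ARM-seq axis), multi-mapping against a full genome, batch and
platform effects, and non-exponential survival. Tests passing on this
generator therefore demonstrate the *statistical machinery* recovers
planted structure under idealized reads; they do not certify robustness
to modification-biased quantification on real libraries.

## Problem sizes in the recovery suite

The end-to-end suite runs at desk scale, sized so every experiment is a
faithful miniature of its design: quantification round trip at 20
samples (~100 candidates, zero dispersion); peak recovery at 20 samples
× 1e5 reads; DE null calibration at 1000+ tRFs, 20 v 20, and sensitivity
at 30 v 30 with 4-fold effects; subtype recovery at one 60-tumor cohort
(k 2–6, 50 restarts) with an independent validation cohort;
superclusters over six 40-tumor cohorts; the driver screen over six
cohorts of 150 tumors / 20 normals (TCGA cohorts run to hundreds of
tumors) with 20 seeded replicates; survival calibration at n = 250 with
~60% events.

## Known limitations

* Exact-sequence assignment cannot see fragments with untemplated
  additions, internal modifications read as mismatches, or trimming
  heterogeneity beyond whole-nucleotide lengths.
* The multi-condition cleavage score is one of several defensible
  generalizations of the pairwise JS; both offered variants agree at the
  endpoints but differ in curvature between them.
* Fisher combination treats correlated evidence as independent (above).
* NMF consensus clustering is stochastic by construction; determinism
  holds for a fixed seed, n_runs and scikit-learn version.
* The signature catalogue and program map are user inputs; the bundled
  toy catalogue exists to exercise the machinery, not to interpret real
  tumors.
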