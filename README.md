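# trfscape

**tRNA-derived fragment (tRF) landscapes from small RNA-seq.**

Transfer-RNA-derived fragments are short (15–30 nt) non-coding RNAs cut
from mature tRNAs or from pre-tRNA 3′ trailers. They are abundant in
tumor small-RNA libraries, cleaved at tightly regulated positions, and
increasingly implicated as oncogenes and prognostic markers. `trfscape`
is a library (plus a thin `trf` command line) for the full computational
workflow around them, aimed at cancer transcriptomics analysts:

1. **annotation** — build a tRF candidate reference from a tRNA gene FASTA:
   mature forms (introns spliced, 3′ CCA appended), 5′-tRFs (mature
   prefixes), 3′-tRFs (mature suffixes ending in CCA) and 3′U-tRFs
   (trailer fragments ending in the pol-III poly-U tract), with the
   `5'-IleAAT-8-1-L20`-style naming scheme and multi-copy merging.
2. **quantification** — zero-mismatch read assignment (exact sequence
   lookup), RPM normalization, the per-cohort 90th-quantile ≥ 1 RPM
   expression filter, and nucleus/cytoplasm enrichment ratios.
3. **cleavage** — fragment-size profiles, per-tRNA cleavage-position
   landscapes, k-means pattern clustering, and the Jensen–Shannon
   cleavage score

   `JS(e¹, e²) = H((e¹+e²)/2) − (H(e¹)+H(e²))/2`,  `H(e) = −Σᵢ eᵢ log₂ eᵢ`,

   which is 0 for identical cleavage patterns and 1 for disjoint ones;
   for n > 2 distributions the score generalizes to
   `(H(ē) − mean H)/log₂ n`.
4. **differential** — tumor-vs-normal Mann–Whitney tests per tRF
   (BH FDR < 0.01, fold change > 2 gates), global class-level shift
   t-tests, and cross-cohort dysregulation summaries.
5. **subtyping** — NMF consensus clustering (multiplicative KL updates,
   many random restarts, cophenetic-correlation rank selection),
   t-score signature extraction, nearest-centroid projection onto
   validation cohorts, and Kaplan–Meier / log-rank / Cox PH survival
   analysis with clinical covariates.
6. **pancancer** — subtype-vs-rest t-score activity matrices,
   hierarchical superclusters ("clusters of clusters") characterized by
   fragment-size class, and rank-based single-sample gene-set enrichment
   (ssGSEA) for signature/program activity.
7. **drivers** — the driver-tRF screen (recurrent upregulation ∩ worse
   survival, Fisher-combined `P_comb`, BH), tissue-specificity JS scores
   and guilt-by-association co-expression.
8. **simulate** — a synthetic-data generator that emulates multi-cohort
   tumor/normal smRNA-seq with planted cleavage peaks, fold changes,
   subtypes, drivers and survival, with full ground-truth bookkeeping —
   every stage of the package is testable without any download.

## Worked example

`examples/` contains one narrative script per capability. For instance
the cleavage-score example:

```bash
python examples/03_cleavage_score.py
```

prints

```
JS cleavage score across 3 cohorts (5'-tRF size profiles): 0.0008
  -> near 0: tumor types share the same cleavage size preference
mass on the 18-20/23/30 nt peaks per cohort: {'C01': 0.752, 'C02': 0.758, 'C03': 0.748}
per-tRNA cleavage concentration: median 0.148, 0/15 tRNAs above the 0.5 hotspot line
k-means cleavage-pattern clusters (tRNAs per cluster): {0: 7, 1: 5, 2: 3}
```

Reading: the three simulated cohorts share one size preference, so their
profiles diverge by almost nothing (JS ≈ 0); roughly three quarters of
5′-tRF mass sits on the three canonical size peaks (18–20, 23 and 30 nt);
and per-tRNA cleavage concentration is scored against a uniform
background, with a 0.5 hotspot line. The driver-screen example
(`examples/06_driver_screen.py`) similarly plants one oncogenic tRF and
prints its recovery:

```
planted driver: 5'-GluCTC-1-1-L18 (active in C01, C02, C03)
screen: 1 driver(s) called of 359 tested tRFs
  5'-GluCTC-1-1-L18: up in 3 cohorts, risky in 3, P_comb = 1.25e-36
tissue-specificity JS of the driver: 0.064 (cohort median 0.015)
```

An end-to-end run from the shell:

```bash
trf simulate --seed 1 -o demo
trf build-ref --trna demo/trna_genes.fasta -o demo/ref
trf quantify --ref demo/ref --fastq-dir demo/fastq \
    --meta demo/fastq/metadata.tsv -o demo/quant
```

## Layout

```
src/trfscape/     library modules (annotation, quantify, cleavage,
                  differential, subtyping, pancancer, drivers, simulate,
                  io, pipeline, cli)
examples/         one narrative script per capability
tests/            pytest suite incl. the end-to-end recovery suite
docs/methods.md   models, parameters, numerical choices, limitations
```
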