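"""NMF expression subtypes, signatures, projection and survival.

A 60-tumor cohort carries three planted subtypes, each upweighting one
3'-tRF size class. NMF consensus clustering recovers the subtype count by
cophenetic correlation, subtype-specific signatures are extracted with a
t-score schema and projected onto an independent validation cohort, and
the groups are compared by log-rank test and Cox proportional hazards.
"""

from sklearn.metrics import adjusted_rand_score

from trfscape import (
    SimulationConfig,
    extract_signatures,
    nmf_consensus,
    project_signatures,
    simulate_study,
    survival_analysis,
)

disc = simulate_study(SimulationConfig(seed=5, n_cohorts=1, n_tumor=60,
                                       n_normal=0, n_trna_genes=12,
                                       subtype_k=3))
val = simulate_study(SimulationConfig(seed=6, n_cohorts=1, n_tumor=60,
                                      n_normal=0, n_trna_genes=12,
                                      subtype_k=3))

model = nmf_consensus(disc.expression_matrix(), cohort="C01",
                      trf_class="three_prime", k_range=(2, 6),
                      n_runs=30, seed=0)
truth = disc.truth.samples.loc[model.assignments.index, "subtype"]
print(f"consensus rank selection: k = {model.k} "
      f"(cophenetic per k: "
      f"{ {k: round(v, 3) for k, v in model.cophenetic.items()} })")
print(f"ARI vs planted subtypes: "
      f"{adjusted_rand_score(truth, model.assignments):.3f}")

sigs = extract_signatures(model, disc.expression_matrix())
for s, sig in sigs.signatures.items():
    lo, hi = sigs.length_summary[s]
    print(f"  subtype {s}: {len(sig)} signature tRFs, sizes {lo}-{hi} nt")

val_assign = project_signatures(sigs, val.expression_matrix())
print("validation subtype proportions:",
      val_assign.value_counts(normalize=True).round(2).sort_index().to_dict())

clinical = disc.truth.samples
res = survival_analysis(model.assignments, clinical)
print(f"log-rank p across subtypes: {res.logrank_p:.3g}")
for contrast, hr in res.hazard_ratios.items():
    print(f"  Cox HR {contrast}: {hr['hr']:.2f} "
          f"({hr['ci_low']:.2f}-{hr['ci_high']:.2f})")
# Without a planted driver the subtypes carry no survival signal, so the
# log-rank p is large and the HRs hover around 1 -- the null behaves.
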