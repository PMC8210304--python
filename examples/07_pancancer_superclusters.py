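"""Cross-cancer superclusters and signature activity.

Subtypes from six cohorts are summarized by subtype-vs-rest t-scores per
tRF, hierarchically clustered into three superclusters ("clusters of
clusters"), and characterized by their dominant fragment-size class and by
rank-based single-sample enrichment (ssGSEA) of a toy signature catalogue.
"""

from trfscape import (
    PlantedDriver,
    SimulationConfig,
    build_activity_matrix,
    emit_expression_resources,
    nmf_consensus,
    signature_activity,
    simulate_study,
    ssgsea,
    supercluster,
)

study = simulate_study(SimulationConfig(
    seed=8, n_cohorts=6, n_tumor=40, n_normal=0, n_trna_genes=12,
    subtype_k=3,
    drivers=(PlantedDriver(fold=1.0, hazard_ratio=2.0,
                           cohorts=tuple(f"C{i:02d}" for i in range(1, 7))),),
))
matrix = study.expression_matrix()

matrices, models = {}, {}
for i, cohort in enumerate(matrix.cohorts):
    mm = matrix.subset(cohort=cohort)
    models[cohort] = nmf_consensus(mm, trf_class="three_prime",
                                   k_range=(2, 4), n_runs=15, seed=i)
    matrices[cohort] = mm

activity = build_activity_matrix(matrices, models, trf_class="three_prime")
labels, composition, modal = supercluster(activity, n_clusters=3,
                                          lengths=matrix.features["length"])
print(f"activity matrix: {activity.shape[0]} tRFs x "
      f"{activity.shape[1]} (cohort, subtype) columns")
print("supercluster sizes:", labels.value_counts().sort_index().to_dict())
print("size-class composition per supercluster:")
print(composition.round(2).to_string())
print("modal size class:", modal.to_dict())

gene_expr, gmt, program_map = emit_expression_resources(study, n_genes=200)
scores = ssgsea(gene_expr, gmt)
act = signature_activity(scores, models, program_map,
                         superclusters=labels, top_n=5)
print("top gene program per supercluster:", act.top_program)
# The toy catalogue plants no program-subtype link, so the program calls
# above are weak or tied (None); the size-class composition is the planted
# signal and is recovered cleanly.
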