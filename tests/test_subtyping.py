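import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from trfscape import (
    SimulationConfig,
    extract_signatures,
    nmf_consensus,
    project_signatures,
    simulate_study,
    simulate_survival,
    survival_analysis,
)
from trfscape.quantify import ExpressionMatrix
from trfscape.subtyping import SubtypingError, preprocess_for_nmf, subtype_t_scores


@pytest.fixture(scope="module")
def subtype_study():
    return simulate_study(
        SimulationConfig(seed=21, n_cohorts=1, n_tumor=45, n_normal=0,
                         n_trna_genes=10, subtype_k=3)
    )


@pytest.fixture(scope="module")
def subtype_model(subtype_study):
    return nmf_consensus(
        subtype_study.expression_matrix(), cohort="C01",
        trf_class="three_prime", k_range=(2, 4), n_runs=12, seed=0,
    )


class TestNmfConsensus:
    def test_recovers_planted_subtypes(self, subtype_study, subtype_model):
        assert subtype_model.k == 3
        truth = subtype_study.truth.samples.loc[
            subtype_model.assignments.index, "subtype"
        ]
        assert adjusted_rand_score(truth, subtype_model.assignments) >= 0.9

    def test_consensus_and_cophenetic_ranges(self, subtype_model):
        c = subtype_model.consensus.values
        assert ((c >= 0) & (c <= 1)).all()
        assert np.allclose(np.diag(c), 1.0)
        assert np.allclose(c, c.T)
        assert all(-1 <= v <= 1 for v in subtype_model.cophenetic.values())

    def test_duplicated_samples_always_coassigned(self, subtype_study):
        m = subtype_study.expression_matrix()
        dup = m.counts.copy()
        dup["C01_T001_copy"] = dup["C01_T001"]
        samples = pd.concat(
            [m.samples, m.samples.loc[["C01_T001"]].rename(
                index={"C01_T001": "C01_T001_copy"})]
        )
        totals = pd.concat(
            [m.totals, pd.Series({"C01_T001_copy": m.totals["C01_T001"]})]
        )
        mm = ExpressionMatrix(counts=dup, totals=totals, samples=samples,
                              features=m.features)
        model = nmf_consensus(mm, trf_class="three_prime",
                              k_range=(2, 3), n_runs=10, seed=1)
        assert model.consensus.loc["C01_T001", "C01_T001_copy"] == pytest.approx(1.0)

    def test_sample_order_invariance(self, subtype_study):
        m = subtype_study.expression_matrix()
        shuffled_cols = list(m.counts.columns)[::-1]
        mm = ExpressionMatrix(
            counts=m.counts[shuffled_cols], totals=m.totals[shuffled_cols],
            samples=m.samples.loc[shuffled_cols], features=m.features,
        )
        a = nmf_consensus(m, trf_class="three_prime", k_range=(3, 3),
                          n_runs=8, seed=2)
        b = nmf_consensus(mm, trf_class="three_prime", k_range=(3, 3),
                          n_runs=8, seed=2)
        assert a.assignments.sort_index().equals(b.assignments.sort_index())

    def test_preprocess_keeps_nonnegativity(self, subtype_study):
        x = preprocess_for_nmf(subtype_study.expression_matrix().rpm)
        assert (x.values >= 0).all()

    def test_too_large_k_rejected(self, subtype_study):
        with pytest.raises(SubtypingError):
            nmf_consensus(subtype_study.expression_matrix(),
                          trf_class="three_prime", k_range=(2, 60), n_runs=2)


class TestSignatures:
    def test_exclusive_expression_assigned_to_its_subtype(self):
        rng = np.random.default_rng(0)
        base = rng.lognormal(2, 0.1, size=(10, 30))
        base[0, 10:20] *= 50  # tRF 0 expressed only in subtype-2 samples
        values = pd.DataFrame(base, index=[f"t{i}" for i in range(10)],
                              columns=[f"s{j}" for j in range(30)])
        assignments = pd.Series([1] * 10 + [2] * 10 + [3] * 10,
                                index=values.columns)
        t = subtype_t_scores(np.log2(values + 1), assignments)
        assert t.loc["t0"].idxmax() == 2
        assert t.loc["t0", 1] < 0 and t.loc["t0", 3] < 0

    def test_constant_feature_scores_zero(self):
        values = pd.DataFrame(np.ones((3, 12)), index=list("abc"),
                              columns=[f"s{j}" for j in range(12)])
        assignments = pd.Series([1] * 6 + [2] * 6, index=values.columns)
        t = subtype_t_scores(values, assignments)
        assert (t.values == 0).all()

    def test_planted_signatures_recovered_in_correct_subtype(
        self, subtype_study, subtype_model
    ):
        sigs = extract_signatures(subtype_model, subtype_study.expression_matrix())
        truth = subtype_study.truth.samples
        arch = subtype_study.truth.subtype_archetype
        from trfscape.simulate import size_class_of

        lengths = subtype_study.expression_matrix().features["length"]
        correct = total = 0
        for subtype, sig in sigs.signatures.items():
            members = subtype_model.assignments.index[
                subtype_model.assignments == subtype
            ]
            planted = arch[int(truth.loc[members, "subtype"].mode()[0])]
            for trf, _score in sig:
                total += 1
                correct += size_class_of(int(lengths[trf])) == planted
        assert total > 0 and correct / total >= 0.9

    def test_length_summary_within_class_bins(self, subtype_study, subtype_model):
        sigs = extract_signatures(subtype_model, subtype_study.expression_matrix())
        for lo, hi in sigs.length_summary.values():
            assert 15 <= lo <= hi <= 30


class TestProjection:
    def test_self_projection_consistency(self, subtype_study, subtype_model):
        m = subtype_study.expression_matrix()
        sigs = extract_signatures(subtype_model, m)
        assigned = project_signatures(sigs, m)
        agreement = (
            assigned.loc[subtype_model.assignments.index]
            == subtype_model.assignments
        ).mean()
        assert agreement >= 0.95

    def test_centroid_sample_assigned_to_its_subtype(
        self, subtype_study, subtype_model
    ):
        m = subtype_study.expression_matrix()
        sigs = extract_signatures(subtype_model, m)
        val = m.subset(samples=subtype_model.assignments.index[:20])
        assigned = project_signatures(sigs, val)
        assert set(assigned.unique()) <= set(sigs.signatures)

    def test_no_shared_trfs_rejected(self, subtype_study, subtype_model):
        m = subtype_study.expression_matrix()
        sigs = extract_signatures(subtype_model, m)
        alien = ExpressionMatrix(
            counts=pd.DataFrame({"s1": [1], "s2": [2]}, index=["other"]),
            totals=pd.Series({"s1": 100, "s2": 100}),
            samples=pd.DataFrame({"cohort": "X", "condition": "tumor"},
                                 index=["s1", "s2"]),
        )
        with pytest.raises(SubtypingError):
            project_signatures(sigs, alien)


class TestSurvival:
    def test_identical_groups_flat(self):
        df = simulate_survival(n=200, hazard_ratio=1.0, seed=3)
        assignments = pd.Series(
            [1, 2] * 100, index=df.index, name="subtype"
        )
        res = survival_analysis(assignments, df)
        assert res.logrank_p > 0.05
        hr = res.hazard_ratios["2_vs_1"]
        assert hr["ci_low"] <= 1.0 <= hr["ci_high"]

    def test_planted_group_hazard_detected(self):
        rng = np.random.default_rng(4)
        n = 150
        groups = pd.Series([1] * n + [2] * n,
                           index=[f"S{i:04d}" for i in range(2 * n)])
        h = np.where(groups == 2, 2.0 / 1000, 1.0 / 1000)
        t_event = rng.exponential(1.0 / h)
        t_cens = rng.exponential(1500.0, size=2 * n)
        clinical = pd.DataFrame(
            {"os_time": np.minimum(t_event, t_cens),
             "os_event": (t_event <= t_cens).astype(int)},
            index=groups.index,
        )
        res = survival_analysis(groups, clinical)
        assert res.logrank_p < 0.001
        hr = res.hazard_ratios["2_vs_1"]
        assert hr["ci_low"] <= 2.0 <= hr["ci_high"]
        assert hr["hr"] > 1.4

    def test_covariate_adjustment_runs(self):
        df = simulate_survival(n=200, hazard_ratio=2.0, seed=5)
        clinical = df.copy()
        clinical["stage"] = np.tile([1, 2, 3, 4], 50)
        groups = pd.Series((df["z"] > 0).astype(int) + 1, index=df.index)
        res = survival_analysis(groups, clinical, covariates=["stage"])
        assert res.covariates == ["stage"]
        assert res.hazard_ratios["2_vs_1"]["hr"] > 1.0

    def test_degenerate_single_sample_group_rejected(self):
        clinical = pd.DataFrame(
            {"os_time": [5.0, 6.0, 7.0], "os_event": [1, 1, 0]},
            index=["a", "b", "c"],
        )
        groups = pd.Series({"a": 1, "b": 1, "c": 2})
        with pytest.raises(SubtypingError):
            survival_analysis(groups, clinical)
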