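import numpy as np
import pandas as pd
import pytest

from trfscape import overlap_fraction, ssgsea
from trfscape.pancancer import (
    PancancerError,
    build_activity_matrix,
    signature_activity,
    supercluster,
)
from trfscape.subtyping import SubtypeModel


def toy_model(assignments: dict) -> SubtypeModel:
    s = pd.Series(assignments, name="subtype")
    n = len(s)
    return SubtypeModel(
        cohort=None, trf_class=None, k=s.nunique(), assignments=s,
        consensus=pd.DataFrame(np.eye(n), index=s.index, columns=s.index),
        cophenetic={s.nunique(): 1.0},
    )


def toy_matrix(values: pd.DataFrame, cohort="A", lengths=None):
    from trfscape.quantify import ExpressionMatrix

    samples = pd.DataFrame(
        {"cohort": cohort, "condition": "tumor"}, index=values.columns
    )
    feats = pd.DataFrame(
        {
            "trf_class": "three_prime",
            "length": lengths if lengths is not None else 20,
            "parents": "fam",
        },
        index=values.index,
    )
    return ExpressionMatrix(
        counts=values, totals=pd.Series(1_000_000, index=values.columns),
        samples=samples, features=feats,
    )


class TestActivityMatrix:
    def test_constant_feature_scores_zero_and_exclusive_feature_signs(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(
            rng.lognormal(4, 0.1, size=(3, 12)),
            index=["const", "sub1_only", "flat"],
            columns=[f"s{i}" for i in range(12)],
        )
        vals.loc["const"] = 100.0
        vals.loc["sub1_only", vals.columns[:6]] *= 40
        m = toy_matrix(vals)
        model = toy_model({f"s{i}": (1 if i < 6 else 2) for i in range(12)})
        act = build_activity_matrix({"A": m}, {"A": model}, min_cohorts=1)
        assert act.loc["const"].abs().max() == 0.0
        assert act.loc["sub1_only", ("A", 1)] > 0
        assert act.loc["sub1_only", ("A", 2)] < 0

    def test_presence_threshold_excludes_rare_features(self):
        rng = np.random.default_rng(1)

        def mk(cohort, trfs):
            vals = pd.DataFrame(
                rng.lognormal(4, 0.5, size=(len(trfs), 8)),
                index=trfs, columns=[f"{cohort}{i}" for i in range(8)],
            )
            return toy_matrix(vals, cohort=cohort)

        matrices = {
            "A": mk("A", ["t1", "t2"]),
            "B": mk("B", ["t1", "t2"]),
            "C": mk("C", ["t1"]),
        }
        models = {
            c: toy_model({f"{c}{i}": (1 if i < 4 else 2) for i in range(8)})
            for c in matrices
        }
        act = build_activity_matrix(matrices, models, min_cohorts=3)
        assert list(act.index) == ["t1"]
        act2 = build_activity_matrix(matrices, models, min_cohorts=2)
        assert set(act2.index) == {"t1", "t2"}

    def test_missing_model_skipped(self):
        rng = np.random.default_rng(2)
        vals = pd.DataFrame(rng.lognormal(4, 0.3, size=(2, 8)),
                            index=["t1", "t2"],
                            columns=[f"s{i}" for i in range(8)])
        m = toy_matrix(vals)
        model = toy_model({f"s{i}": (1 if i < 4 else 2) for i in range(8)})
        act = build_activity_matrix({"A": m, "B": m}, {"A": model}, min_cohorts=1)
        assert set(act.columns.get_level_values("cohort")) == {"A"}
        with pytest.raises(PancancerError):
            build_activity_matrix({"A": m}, {}, min_cohorts=1)


class TestSupercluster:
    @staticmethod
    def _archetype_activity(n_cohorts=6, seed=0):
        rng = np.random.default_rng(seed)
        trfs = [f"t{i}" for i in range(30)]
        lengths = pd.Series(
            [16 + (i % 3) * 6 for i in range(30)], index=trfs
        )  # 16/22/28 -> the three size classes
        cols, truth = {}, {}
        for c in range(n_cohorts):
            for arch in range(3):
                col = (f"C{c}", arch + 1)
                base = rng.normal(0, 0.3, size=30)
                boost = np.array(
                    [3.0 if (i % 3) == arch else -1.0 for i in range(30)]
                )
                cols[col] = base + boost
                truth[col] = arch
        act = pd.DataFrame(cols)
        act.index = trfs
        act.columns = pd.MultiIndex.from_tuples(act.columns,
                                                names=["cohort", "subtype"])
        return act, lengths, truth

    def test_recovers_planted_archetypes(self):
        from sklearn.metrics import adjusted_rand_score

        act, lengths, truth = self._archetype_activity()
        labels, comp, modal = supercluster(act, 3, lengths=lengths)
        ari = adjusted_rand_score([truth[c] for c in labels.index], labels.values)
        assert ari == 1.0
        assert np.allclose(comp.sum(axis=1), 1.0)
        assert set(modal) <= {"18nt", "22nt", "24nt"}
        # each supercluster is dominated by a distinct size class
        assert modal.nunique() == 3

    def test_column_order_invariance_and_duplicates_cocluster(self):
        act, lengths, truth = self._archetype_activity()
        labels_a, _, _ = supercluster(act, 3, lengths=lengths)
        shuffled = act[list(act.columns)[::-1]]
        labels_b, _, _ = supercluster(shuffled, 3, lengths=lengths)
        # same partition (label names may permute)
        from sklearn.metrics import adjusted_rand_score

        joined = pd.concat([labels_a.rename("a"), labels_b.rename("b")], axis=1)
        assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0
        dup_pair = [act.columns[0], act.columns[3]]
        assert truth[dup_pair[0]] == truth[dup_pair[1]]
        assert labels_a[dup_pair[0]] == labels_a[dup_pair[1]]

    def test_too_few_columns_rejected(self):
        act, lengths, _ = self._archetype_activity(n_cohorts=1)
        with pytest.raises(PancancerError):
            supercluster(act[[act.columns[0], act.columns[1]]], 3)


@pytest.fixture(scope="module")
def profile():
    rng = np.random.default_rng(3)
    return pd.DataFrame(
        rng.standard_normal((300, 4)),
        index=[f"G{i}" for i in range(300)], columns=list("wxyz"),
    )


class TestSsgsea:

    def test_top_ranked_set_is_extremal(self, profile):
        top20 = list(profile.index[np.argsort(-profile["w"].values)[:20]])
        rng = np.random.default_rng(4)
        sets = {"top": top20}
        for i in range(30):
            sets[f"r{i}"] = list(rng.choice(profile.index, 20, replace=False))
        scores = ssgsea(profile, sets)
        assert scores.loc["top", "w"] == scores["w"].max()

    def test_monotone_transform_invariance(self, profile):
        sets = {"s": list(profile.index[:25])}
        a = ssgsea(profile, sets)
        b = ssgsea(np.exp(profile * 2.0) + 5, sets)
        assert np.allclose(a.values, b.values)

    def test_permutation_null_centered_at_zero(self, profile):
        rng = np.random.default_rng(5)
        x = profile[["w"]]
        scores = []
        for _ in range(500):
            genes = rng.choice(profile.index, 20, replace=False)
            scores.append(ssgsea(x, {"s": list(genes)}).iloc[0, 0])
        scores = np.asarray(scores)
        se = scores.std(ddof=1) / np.sqrt(len(scores))
        assert abs(scores.mean()) < 2 * se + 1e-9

    def test_small_sets_skipped(self, profile):
        with pytest.raises(PancancerError):
            ssgsea(profile, {"tiny": list(profile.index[:3])})


class TestSignatureActivity:
    def test_planted_program_is_top_call(self):
        rng = np.random.default_rng(6)
        n_sig, n_samp = 30, 24
        sigs = [f"sig{i}" for i in range(n_sig)]
        scores = pd.DataFrame(
            rng.normal(0, 0.2, size=(n_sig, n_samp)),
            index=sigs, columns=[f"s{i}" for i in range(n_samp)],
        )
        # program-P signatures activated in subtype 1
        scores.iloc[:10, :12] += 3.0
        model = toy_model({f"s{i}": (1 if i < 12 else 2) for i in range(n_samp)})
        programs = pd.Series(
            {s: ("P" if i < 10 else f"Q{i % 3}") for i, s in enumerate(sigs)}
        )
        sclust = pd.Series(
            {("A", 1): 1, ("A", 2): 2},
        )
        sclust.index = pd.MultiIndex.from_tuples(sclust.index)
        res = signature_activity(scores, {"A": model}, programs,
                                 superclusters=sclust, top_n=10)
        assert res.top_program[1] == "P"
        assert res.t_scores.loc["sig0", ("A", 1)] > 0

    def test_all_zero_scores_tie_reported(self):
        scores = pd.DataFrame(
            np.zeros((6, 8)), index=[f"sig{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(8)],
        )
        model = toy_model({f"s{i}": (1 if i < 4 else 2) for i in range(8)})
        programs = pd.Series({f"sig{i}": f"P{i % 2}" for i in range(6)})
        res = signature_activity(scores, {"A": model}, programs)
        assert all(v is None for v in res.top_program.values())

    def test_quantile_ranking_matches_direct_computation(self):
        rng = np.random.default_rng(7)
        scores = pd.DataFrame(
            rng.normal(size=(8, 12)), index=[f"sig{i}" for i in range(8)],
            columns=[f"s{i}" for i in range(12)],
        )
        model = toy_model({f"s{i}": (i % 3 + 1) for i in range(12)})
        programs = pd.Series({f"sig{i}": "P" for i in range(8)})
        res = signature_activity(scores, {"A": model}, programs)
        ranked = res.ranking[1]
        direct = res.t_scores.quantile(0.25, axis=1).sort_values(ascending=False)
        assert list(ranked.index) == list(direct.index)
        assert np.allclose(ranked.values, direct.values)


class TestOverlap:
    def test_identity_and_relabeling(self):
        a = pd.Series([1, 1, 2, 2, 3, 3], index=list("abcdef"))
        tab = overlap_fraction(a, a)
        assert np.allclose(np.diag(tab.values), 1.0)
        relabeled = a.map({1: "x", 2: "y", 3: "z"})
        tab2 = overlap_fraction(a, relabeled)
        assert np.allclose(tab2.values.max(axis=1), 1.0)
        assert np.allclose(tab2.values.sum(axis=1), 1.0)

    def test_independent_assignments_near_marginals(self):
        rng = np.random.default_rng(8)
        idx = [f"s{i}" for i in range(4000)]
        a = pd.Series(rng.integers(1, 4, size=4000), index=idx)
        b = pd.Series(rng.choice(["u", "v"], p=[0.7, 0.3], size=4000), index=idx)
        tab = overlap_fraction(a, b)
        assert np.allclose(tab["u"], 0.7, atol=0.05)

    def test_disjoint_sample_sets_rejected(self):
        a = pd.Series([1], index=["a"])
        b = pd.Series([1], index=["b"])
        with pytest.raises(PancancerError):
            overlap_fraction(a, b)
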