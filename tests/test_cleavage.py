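import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trfscape import cleavage as clv
from trfscape.cleavage import CleavageDistribution


def dist(*probs, labels=None):
    labels = labels if labels is not None else tuple(range(len(probs)))
    return CleavageDistribution(labels, np.array(probs, dtype=float))


def brute_force_generalized_js(vectors):
    """Independent oracle: direct entropy summation in pure Python."""

    def h(p):
        return -math.fsum(x * math.log2(x) for x in p if x > 0)

    n = len(vectors)
    mean = [math.fsum(v[i] for v in vectors) / n for i in range(len(vectors[0]))]
    return (h(mean) - math.fsum(h(v) for v in vectors) / n) / math.log2(n)


prob_vectors = st.integers(2, 12).flatmap(
    lambda n: st.lists(st.floats(1e-6, 1.0), min_size=n, max_size=n)
).map(lambda w: tuple(x / sum(w) for x in w))


class TestEntropy:
    def test_point_mass_is_zero(self):
        assert clv.shannon_entropy(dist(1.0, 0.0, 0.0)) == 0.0

    def test_uniform_two_is_one_bit(self):
        assert clv.shannon_entropy(dist(0.5, 0.5)) == pytest.approx(1.0, abs=1e-12)

    def test_closed_form(self):
        assert clv.shannon_entropy(dist(0.5, 0.25, 0.25)) == pytest.approx(
            1.5, abs=1e-12
        )

    def test_unnormalized_rejected(self):
        with pytest.raises(clv.CleavageError):
            dist(0.5, 0.4)


class TestJsDivergence:
    def test_identical_distributions_score_zero(self):
        d = dist(0.3, 0.3, 0.4)
        assert clv.js_divergence(d, d) == 0.0

    def test_disjoint_point_masses_score_one(self):
        assert clv.js_divergence(dist(1.0, 0.0), dist(0.0, 1.0)) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_closed_form_hand_value(self):
        # H(0.75, 0.25) - (1 + 0)/2
        expected = -(0.75 * math.log2(0.75) + 0.25 * math.log2(0.25)) - 0.5
        got = clv.js_divergence(dist(0.5, 0.5), dist(1.0, 0.0))
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.3112781244591, abs=1e-10)

    def test_label_mismatch_rejected(self):
        with pytest.raises(clv.CleavageError):
            clv.js_divergence(dist(1.0, 0.0, labels=(1, 2)),
                              dist(1.0, 0.0, labels=(3, 4)))

    @settings(derandomize=True, max_examples=50)
    @given(prob_vectors, st.randoms(use_true_random=False))
    def test_metric_properties(self, p, rnd):
        q = list(p)
        rnd.shuffle(q)
        d1, d2 = dist(*p), dist(*q)
        a, b = clv.js_divergence(d1, d2), clv.js_divergence(d2, d1)
        assert a == pytest.approx(b, abs=1e-12)  # symmetry
        assert -1e-12 <= a <= 1 + 1e-12  # bounded
        assert clv.js_divergence(d1, d1) == 0.0  # identity


class TestGeneralizedScore:
    def test_identical_collection_scores_zero(self):
        d = dist(0.2, 0.5, 0.3)
        assert clv.js_cleavage_score([d, d, d]) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n", [2, 3, 4, 8])
    def test_disjoint_point_masses_score_one(self, n):
        ds = [CleavageDistribution(tuple(range(n)), np.eye(n)[i]) for i in range(n)]
        assert clv.js_cleavage_score(ds) == pytest.approx(1.0, abs=1e-12)

    def test_equals_pairwise_at_n2(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            k = rng.integers(2, 10)
            p = rng.dirichlet(np.ones(k))
            q = rng.dirichlet(np.ones(k))
            d1 = CleavageDistribution(tuple(range(k)), p)
            d2 = CleavageDistribution(tuple(range(k)), q)
            assert clv.js_cleavage_score([d1, d2]) == pytest.approx(
                clv.js_divergence(d1, d2), abs=1e-12
            )

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(1000):
            n = int(rng.integers(2, 7))
            k = int(rng.integers(2, 17))
            vecs = [rng.dirichlet(np.ones(k)) for _ in range(n)]
            ds = [CleavageDistribution(tuple(range(k)), v) for v in vecs]
            got = clv.js_cleavage_score(ds)
            want = brute_force_generalized_js([list(v) for v in vecs])
            worst = max(worst, abs(got - want))
        assert worst < 1e-12

    def test_cabili_variant_is_sqrt_with_same_endpoints(self):
        d = dist(0.2, 0.5, 0.3)
        assert clv.js_cleavage_score([d, d], method="cabili") == 0.0
        e1, e2 = dist(1.0, 0.0), dist(0.0, 1.0)
        assert clv.js_cleavage_score([e1, e2], method="cabili") == pytest.approx(1.0)
        g = clv.js_cleavage_score([d, dist(0.6, 0.2, 0.2)])
        c = clv.js_cleavage_score([d, dist(0.6, 0.2, 0.2)], method="cabili")
        assert c == pytest.approx(math.sqrt(g), abs=1e-12)

    def test_single_distribution_rejected(self):
        with pytest.raises(clv.CleavageError):
            clv.js_cleavage_score([dist(1.0, 0.0)])


class TestProfilesAndLandscape:
    def test_size_profile_sums_to_one_and_identical_groups_score_zero(
        self, small_matrix
    ):
        profiles = clv.size_profile(small_matrix, "five_prime", group_by="cohort")
        assert set(profiles) == {"C01", "C02"}
        for d in profiles.values():
            assert d.e.sum() == pytest.approx(1.0, abs=1e-9)
        same = clv.js_cleavage_score([profiles["C01"], profiles["C01"]])
        assert same == pytest.approx(0.0, abs=1e-12)

    def test_point_mass_when_single_size_expressed(self, small_matrix):
        sub = small_matrix.subset(
            trfs=[t for t in small_matrix.rpm.index
                  if t.startswith("5'") and t.endswith("L22")]
        )
        profiles = clv.size_profile(sub, "five_prime")
        for d in profiles.values():
            assert d.e[d.labels.index(22)] == pytest.approx(1.0)

    def test_landscape_rows_normalized_with_concentration(self, small_matrix):
        landscape, conc = clv.position_landscape(small_matrix, "five_prime")
        assert np.allclose(landscape.sum(axis=1), 1.0)
        assert ((conc >= 0) & (conc <= 1)).all()

    def test_concentration_closed_form_for_point_mass(self):
        labels = tuple(range(15, 31))
        point = CleavageDistribution.point_mass(labels, 19)
        uniform = CleavageDistribution.uniform(labels)
        expected = clv.js_divergence(point, uniform)
        # family expressing a single length is maximally concentrated
        assert expected == pytest.approx(
            clv.js_divergence(CleavageDistribution.point_mass(labels, 25), uniform)
        )
        assert 0 < expected < 1

    def test_hotspot_threshold(self):
        import pandas as pd

        conc = pd.Series({"a": 0.7, "b": 0.2})
        calls = clv.call_hotspots(conc, threshold=0.5)
        assert calls.to_dict() == {"a": True, "b": False}


class TestClusterPatterns:
    @staticmethod
    def _two_archetype_landscape(n_per=8, seed=0):
        import pandas as pd

        rng = np.random.default_rng(seed)
        rows, truth = {}, {}
        for i in range(n_per * 2):
            base = np.full(16, 0.01)
            if i < n_per:
                base[3] = 1.0
                truth[f"fam{i:02d}"] = 0
            else:
                base[12] = 1.0
                truth[f"fam{i:02d}"] = 1
            base += rng.uniform(0, 0.02, 16)
            rows[f"fam{i:02d}"] = base / base.sum()
        return pd.DataFrame(rows, index=range(15, 31)).T, truth

    def test_recovers_two_planted_archetypes(self):
        from sklearn.metrics import adjusted_rand_score

        landscape, truth = self._two_archetype_landscape()
        labels, order = clv.cluster_cleavage_patterns(landscape, k=2, seed=0)
        ari = adjusted_rand_score([truth[f] for f in labels.index], labels.values)
        assert ari == 1.0
        assert set(order) == set(landscape.index)

    def test_row_order_invariance(self):
        landscape, _ = self._two_archetype_landscape()
        labels_a, order_a = clv.cluster_cleavage_patterns(landscape, k=2, seed=1)
        shuffled = landscape.sample(frac=1.0, random_state=3)
        labels_b, order_b = clv.cluster_cleavage_patterns(shuffled, k=2, seed=1)
        assert labels_a.sort_index().equals(labels_b.sort_index())
        assert order_a == order_b

    def test_k_validation(self):
        landscape, _ = self._two_archetype_landscape(n_per=2)
        with pytest.raises(clv.CleavageError):
            clv.cluster_cleavage_patterns(landscape, k=50)
        with pytest.raises(clv.CleavageError):
            clv.cluster_cleavage_patterns(landscape, k=1)
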