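"""Semantic similarity, GIP kernels, integration and normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mdanet.io_data import DiseaseOntology, SimilarityMatrix
from mdanet.similarity import (
    GipConfig,
    default_mask,
    disease_semantic_similarity,
    gip_kernel,
    information_content,
    integrate_similarity,
    laplacian_normalize,
    semantic_contributions,
    semantic_similarity_pair,
    semantic_value,
)


class TestSemanticContributions:
    def test_parent_chain_decays(self, chain_ontology):
        c = semantic_contributions(chain_ontology, "d", delta=0.5)
        assert c == {"d": 1.0, "p": 0.5, "g": 0.25}

    def test_root_only(self, sibling_ontology):
        assert semantic_contributions(sibling_ontology, "d3") == {"d3": 1.0}

    def test_multi_path_takes_max(self):
        # diamond: d -> a -> t and d -> t directly; t reachable at depth 1 and 2
        ont = DiseaseOntology({"d": [("d", "a"), ("a", "t"), ("d", "t")]})
        c = semantic_contributions(ont, "d", delta=0.5)
        assert c["t"] == 0.5  # direct path wins over 0.25 via a

    def test_semantic_values(self, chain_ontology, sibling_ontology):
        assert semantic_value(semantic_contributions(chain_ontology, "d")) == pytest.approx(1.75)
        assert semantic_value(semantic_contributions(sibling_ontology, "d3")) == 1.0
        assert semantic_value({"d": 1.0, "p": 0.5}) == 1.5


class TestSemanticSimilarityPair:
    def test_self_similarity_is_one(self, sibling_ontology):
        assert semantic_similarity_pair(sibling_ontology, "d1", "d1") == pytest.approx(1.0)

    def test_siblings_share_parent(self, sibling_ontology):
        s = semantic_similarity_pair(sibling_ontology, "d1", "d2", "model1", 0.5)
        assert s == pytest.approx(1.0 / 3.0)

    def test_disjoint_dags_give_zero(self, sibling_ontology):
        assert semantic_similarity_pair(sibling_ontology, "d1", "d3") == 0.0

    def test_symmetric(self, sibling_ontology):
        for model in ("model1", "model2"):
            ab = semantic_similarity_pair(sibling_ontology, "d1", "d2", model)
            ba = semantic_similarity_pair(sibling_ontology, "d2", "d1", model)
            assert ab == pytest.approx(ba)


class TestInformationContent:
    def test_values(self):
        # 10 diseases; node "shared" sits in 5 DAGs, "rare" in 1, "all" in 10
        edges = {}
        for i in range(10):
            d = f"d{i}"
            e = [(d, "all")]
            if i < 5:
                e.append(("all", "shared"))
            if i == 0:
                e.append(("shared", "rare"))
            edges[d] = e
        ont = DiseaseOntology(edges)
        assert information_content(ont, "all") == pytest.approx(0.0)
        assert information_content(ont, "rare") == pytest.approx(2.302585, abs=1e-6)
        assert information_content(ont, "shared") == pytest.approx(0.693147, abs=1e-6)

    def test_model2_similarity_is_log_base_invariant(self, sibling_ontology):
        # rescaling the log base multiplies numerator and denominator alike
        s_nat = semantic_similarity_pair(sibling_ontology, "d1", "d2", "model2")

        def with_base(base):
            scale = 1.0 / np.log(base)
            ci = {k: v * scale for k, v in semantic_contributions(sibling_ontology, "d1", "model2").items()}
            cj = {k: v * scale for k, v in semantic_contributions(sibling_ontology, "d2", "model2").items()}
            shared = set(ci) & set(cj)
            return sum(ci[k] + cj[k] for k in shared) / (sum(ci.values()) + sum(cj.values()))

        assert s_nat == pytest.approx(with_base(2.0))
        assert s_nat == pytest.approx(with_base(10.0))


def _brute_force_semantic(ont, names, delta):
    """Independent recursive oracle on explicit ancestor closures."""

    def contrib1(disease):
        closure = ont.ancestors(disease)
        parents_of = {}
        for c, p in ont.edges(disease):
            parents_of.setdefault(c, []).append(p)

        def rec(node, value, acc):
            acc[node] = max(acc.get(node, 0.0), value)
            for p in parents_of.get(node, []):
                rec(p, value * delta, acc)

        acc = {}
        rec(disease, 1.0, acc)
        assert set(acc) == set(closure)
        return acc

    def contrib2(disease):
        return {k: -np.log(ont.dag_count(k) / ont.n_diseases) for k in ont.ancestors(disease)}

    n = len(names)
    out = np.eye(n)
    for a in range(n):
        for b in range(n):
            if a == b or names[a] not in ont or names[b] not in ont:
                continue
            total = 0.0
            for fn in (contrib1, contrib2):
                ci, cj = fn(names[a]), fn(names[b])
                num = sum(ci[k] + cj[k] for k in set(ci) & set(cj))
                total += num / (sum(ci.values()) + sum(cj.values()))
            out[a, b] = total / 2.0
    return out


class TestDiseaseSemanticSimilarity:
    def test_mean_of_models_matches_brute_force(self):
        from mdanet.synthetic import generate_toy_ontology

        ont = generate_toy_ontology(8, depth=3, seed=5)
        names = ont.diseases
        mat = disease_semantic_similarity(ont, names, delta=0.5)
        oracle = _brute_force_semantic(ont, names, 0.5)
        np.testing.assert_allclose(mat.values, oracle, atol=1e-12)

    def test_uncovered_disease_gets_zero_row(self, sibling_ontology):
        mat = disease_semantic_similarity(sibling_ontology, ("d1", "d2", "unknown"))
        assert mat.values[2, 0] == 0.0 and mat.values[2, 2] == 1.0

    def test_average_of_two_models(self, sibling_ontology):
        s1 = semantic_similarity_pair(sibling_ontology, "d1", "d2", "model1")
        s2 = semantic_similarity_pair(sibling_ontology, "d1", "d2", "model2")
        mat = disease_semantic_similarity(sibling_ontology, ("d1", "d2"))
        assert mat.values[0, 1] == pytest.approx((s1 + s2) / 2)


class TestGipKernel:
    def test_hand_computed_value(self):
        # profiles [1,0,1] and [0,1,0]: gamma = 1/((2+1)/2) = 2/3, dist^2 = 3
        k = gip_kernel(np.array([[1, 0, 1], [0, 1, 0]]), ("a", "b"))
        assert k.values[0, 1] == pytest.approx(np.exp(-2.0), abs=1e-12)

    def test_identical_profiles_give_one(self):
        k = gip_kernel(np.array([[1, 1, 0], [1, 1, 0]]), ("a", "b"))
        assert k.values[0, 1] == pytest.approx(1.0)

    def test_symmetric_unit_diagonal_column_order_invariant(self):
        rng = np.random.default_rng(3)
        prof = (rng.random((10, 15)) < 0.3).astype(float)
        prof[0, 0] = 1  # guard against all-zero
        names = tuple(f"m{i}" for i in range(10))
        k = gip_kernel(prof, names)
        assert np.allclose(k.values, k.values.T)
        assert np.allclose(np.diag(k.values), 1.0)
        perm = rng.permutation(15)
        k2 = gip_kernel(prof[:, perm], names)
        np.testing.assert_allclose(k.values, k2.values, atol=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(arrays(np.int8, (6, 9), elements=st.integers(0, 1)))
    def test_kernel_contract_on_arbitrary_profiles(self, prof):
        prof = prof.astype(float)
        if prof.sum() == 0:
            prof[0, 0] = 1.0
        k = gip_kernel(prof, tuple(f"m{i}" for i in range(6)))
        assert np.allclose(k.values, k.values.T)
        assert np.allclose(np.diag(k.values), 1.0)
        assert (k.values > 0).all() and (k.values <= 1).all()

    def test_all_zero_profiles_error(self):
        with pytest.raises(ZeroDivisionError):
            gip_kernel(np.zeros((3, 4)), ("a", "b", "c"))

    def test_gamma_prime_must_be_positive(self):
        with pytest.raises(ValueError):
            GipConfig(gamma_prime=0.0)


class TestIntegration:
    def _pair(self):
        prim = SimilarityMatrix(np.array([[1.0, 0.0], [0.0, 1.0]]), ("a", "b"))
        gip = SimilarityMatrix(np.array([[1.0, 0.7], [0.7, 1.0]]), ("a", "b"), kind="gip")
        return prim, gip

    def test_mask_all_true_returns_primary(self):
        prim, gip = self._pair()
        out = integrate_similarity(prim, gip, np.ones((2, 2), bool))
        np.testing.assert_array_equal(out.values, prim.values)

    def test_mask_all_false_returns_gip(self):
        prim, gip = self._pair()
        out = integrate_similarity(prim, gip, np.zeros((2, 2), bool))
        np.testing.assert_array_equal(out.values, gip.values)

    def test_default_mask_treats_zero_as_missing(self):
        prim, gip = self._pair()
        out = integrate_similarity(prim, gip)
        assert out.values[0, 1] == 0.7  # zero off-diagonal fell back to GIP

    def test_asymmetric_mask_rejected(self):
        prim, gip = self._pair()
        mask = np.array([[True, True], [False, True]])
        with pytest.raises(ValueError, match="symmetric"):
            integrate_similarity(prim, gip, mask)

    def test_default_mask_keeps_diagonal(self):
        prim, _ = self._pair()
        assert default_mask(prim).diagonal().all()


class TestLaplacianNormalize:
    def test_identity_unchanged(self):
        np.testing.assert_array_equal(laplacian_normalize(np.eye(4)), np.eye(4))

    def test_all_ones_two_by_two(self):
        out = laplacian_normalize(np.ones((2, 2)))
        np.testing.assert_allclose(out, np.full((2, 2), 0.5))

    def test_matches_explicit_triple_product(self, random_similarity):
        s = random_similarity.values
        d = np.diag(1.0 / np.sqrt(s.sum(axis=1)))
        np.testing.assert_allclose(laplacian_normalize(random_similarity), d @ s @ d, atol=1e-9)

    def test_spectrum_in_unit_interval(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            s = rng.random((20, 20))
            s = (s + s.T) / 2
            eig = np.linalg.eigvalsh(laplacian_normalize(s))
            assert eig.min() >= -1 - 1e-9 and eig.max() <= 1 + 1e-9

    def test_zero_row_sum_error(self):
        s = np.zeros((2, 2))
        with pytest.raises(ZeroDivisionError):
            laplacian_normalize(s)
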