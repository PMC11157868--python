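import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circdis import (
    AssociationMatrix,
    DiseaseOntology,
    SimilarityMatrix,
    build_heterogeneous_adjacency,
    circrna_functional_similarity,
    disease_semantic_similarity,
    gip_kernel,
    integrate_similarity,
    semantic_contribution,
    semantic_value,
)


class TestSemanticContribution:
    def test_chain_decays_geometrically(self, chain_ontology):
        sc = semantic_contribution(chain_ontology, "b", gamma=0.5)
        assert sc.contributions == {"b": 1.0, "a": 0.5, "r": 0.25}

    def test_isolated_term_is_base_case(self):
        onto = DiseaseOntology({"d"}, set())
        sc = semantic_contribution(onto, "d", gamma=0.7)
        assert sc.contributions == {"d": 1.0}

    def test_diamond_takes_max_over_paths(self, diamond_ontology):
        sc = semantic_contribution(diamond_ontology, "b", gamma=0.5)
        assert sc.contributions["r"] == pytest.approx(0.25, abs=1e-15)

    def test_unknown_target_errors(self, chain_ontology):
        with pytest.raises(KeyError):
            semantic_contribution(chain_ontology, "zzz")

    def test_semantic_value_sums_contributions(self, chain_ontology, diamond_ontology):
        assert semantic_value(semantic_contribution(chain_ontology, "b")) == 1.75
        assert semantic_value(semantic_contribution(diamond_ontology, "b")) == 2.25


class TestDiseaseSemanticSimilarity:
    def test_diagonal_is_one(self, diamond_ontology):
        DS = disease_semantic_similarity(diamond_ontology, ["r", "a1", "a2", "b"])
        assert np.allclose(np.diag(DS.values), 1.0)

    def test_chain_hand_value(self, chain_ontology):
        DS = disease_semantic_similarity(chain_ontology, ["a", "b"])
        assert DS.values[0, 1] == pytest.approx(2.25 / 3.25, abs=1e-12)

    def test_disjoint_ancestors_give_zero(self):
        onto = DiseaseOntology({"x", "y"}, set())
        DS = disease_semantic_similarity(onto, ["x", "y"])
        assert DS.values[0, 1] == 0.0

    def test_missing_disease_warns_and_isolates(self, chain_ontology):
        with pytest.warns(UserWarning, match="missing"):
            DS = disease_semantic_similarity(chain_ontology, ["b", "ghost"])
        assert DS.values[1, 1] == 1.0 and DS.values[0, 1] == 0.0


class TestFunctionalSimilarity:
    def _assoc(self, values, diseases):
        values = np.asarray(values)
        circ = [f"c{i}" for i in range(values.shape[0])]
        return AssociationMatrix(values, circ, diseases)

    def test_identical_disease_sets_give_one(self, chain_ontology):
        A = self._assoc([[1, 1, 0], [1, 1, 0]], ["a", "b", "r"])
        DS = disease_semantic_similarity(chain_ontology, ["a", "b", "r"])
        FS = circrna_functional_similarity(A, DS)
        assert FS.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_empty_set_gives_zero(self, chain_ontology):
        A = self._assoc([[1, 0], [0, 0]], ["a", "b"])
        DS = disease_semantic_similarity(chain_ontology, ["a", "b"])
        FS = circrna_functional_similarity(A, DS)
        assert FS.values[0, 1] == 0.0
        assert FS.values[1, 1] == 0.0  # unit diagonal only with >=1 association

    def test_singleton_cross_sets_reduce_to_ds(self, chain_ontology):
        A = self._assoc([[1, 0], [0, 1]], ["a", "b"])
        DS = disease_semantic_similarity(chain_ontology, ["a", "b"])
        FS = circrna_functional_similarity(A, DS)
        assert FS.values[0, 1] == pytest.approx(2.25 / 3.25, abs=1e-12)


class TestGipKernel:
    def test_identical_profiles_give_one(self):
        A = AssociationMatrix([[1, 0], [1, 0]], ["c1", "c2"], ["d1", "d2"])
        CK = gip_kernel(A, "circRNA")
        assert CK.values[0, 1] == pytest.approx(1.0, abs=1e-15)

    def test_hand_value_identity_matrix(self):
        A = AssociationMatrix(np.eye(2, dtype=int), ["c1", "c2"], ["d1", "d2"])
        CK = gip_kernel(A, "circRNA")
        # bandwidth 2/2 = 1, squared distance 2 -> exp(-2)
        assert CK.values[0, 1] == pytest.approx(np.exp(-2.0), abs=1e-12)

    def test_entries_in_unit_interval(self, small_dataset):
        A, _ = small_dataset
        for axis in ("circRNA", "disease"):
            K = gip_kernel(A, axis).values
            assert (K > 0).all() and (K <= 1).all()
            assert np.array_equal(np.diag(K), np.ones(K.shape[0]))

    def test_all_zero_matrix_errors(self):
        A = AssociationMatrix([[0], [0]], ["c1", "c2"], ["d1"])
        with pytest.raises(ValueError, match="bandwidth"):
            gip_kernel(A, "circRNA")


class TestIntegrateSimilarity:
    def _sim(self, vals, kind=""):
        ids = [f"i{k}" for k in range(len(vals))]
        return SimilarityMatrix(np.asarray(vals, float), ids, kind)

    def test_primary_wins_where_nonzero(self):
        out = integrate_similarity(
            self._sim([[1, 0], [0, 1]]), self._sim([[1, 0.2], [0.2, 1]])
        )
        assert np.allclose(out.values, [[1, 0.2], [0.2, 1]])

    def test_all_nonzero_primary_passes_through(self):
        prim = self._sim([[1, 0.4], [0.4, 1]])
        out = integrate_similarity(prim, self._sim([[1, 0.9], [0.9, 1]]))
        assert np.allclose(out.values, prim.values)

    def test_all_zero_primary_takes_fallback(self):
        fall = self._sim([[1, 0.3], [0.3, 1]])
        out = integrate_similarity(self._sim([[0, 0], [0, 0]]), fall)
        assert np.allclose(out.values, fall.values)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            integrate_similarity(self._sim([[1.0]]), self._sim([[1, 0], [0, 1]]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_idempotent_with_same_fallback(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(2, 8))
        prim = rng.random((p, p)) * rng.integers(0, 2, (p, p))
        prim = (prim + prim.T) / 2
        np.fill_diagonal(prim, 1.0)
        fall = rng.random((p, p))
        fall = (fall + fall.T) / 2
        np.fill_diagonal(fall, 1.0)
        ids = [f"i{k}" for k in range(p)]
        once = integrate_similarity(
            SimilarityMatrix(prim, ids), SimilarityMatrix(fall, ids)
        )
        twice = integrate_similarity(once, SimilarityMatrix(fall, ids))
        assert np.array_equal(once.values, twice.values)


class TestHeterogeneousAdjacency:
    def test_block_layout(self):
        A = AssociationMatrix([[1], [1]], ["c1", "c2"], ["d1"])
        X = build_heterogeneous_adjacency(A).values
        expect = np.zeros((3, 3))
        expect[0, 2] = expect[1, 2] = expect[2, 0] = expect[2, 1] = 1
        assert np.array_equal(X, expect)

    def test_symmetric_zero_trace(self, small_dataset):
        A, _ = small_dataset
        X = build_heterogeneous_adjacency(A).values
        assert np.array_equal(X, X.T) and np.trace(X) == 0.0
        n = A.n_circ
        assert not X[:n, :n].any() and not X[n:, n:].any()
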