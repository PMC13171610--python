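"""Similarity measures against hand-derived values and brute-force oracles."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridmda.containers import AssociationMatrix, DiseaseDAG, SimilarityMatrix
from hybridmda.similarity import (
    SequenceFeatureVector,
    dag_semantic_contribution,
    dag_semantic_matrix,
    dag_semantic_similarity,
    functional_similarity,
    gipk_bandwidth,
    gipk_similarity,
    integrate_disease_similarity,
    integrate_mirna_similarity,
    kmer_profile,
    sequence_similarity,
    sequence_similarity_matrix,
)

from conftest import random_similarity


def _vec(counts, k=1):
    return SequenceFeatureVector("x", np.asarray(counts), k)


class TestKmerProfile:
    def test_single_window(self):
        prof = kmer_profile("ACGU", k=4)
        assert prof.counts.sum() == 1
        # index of "ACGT": A=0,C=1,G=2,T=3 -> 0*64+1*16+2*4+3 = 27
        assert prof.counts[27] == 1

    def test_homopolymer_counts_windows(self):
        assert kmer_profile("AAAA", k=4).counts[0] == 1
        assert kmer_profile("AAAAA", k=4).counts[0] == 2

    def test_u_and_t_equivalent(self):
        np.testing.assert_array_equal(
            kmer_profile("ACGU", k=2).counts, kmer_profile("acgt", k=2).counts
        )

    def test_short_sequence_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            prof = kmer_profile("ACG", k=4)
        assert prof.counts.sum() == 0

    def test_bad_character_rejected_with_position(self):
        with pytest.raises(ValueError, match="position 2"):
            kmer_profile("ACXGU", k=2)

    def test_window_count_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            L = int(rng.integers(1, 40))
            seq = "".join(rng.choice(list("ACGU"), L))
            k = int(rng.integers(1, 6))
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                prof = kmer_profile(seq, k=k)
            assert prof.counts.sum() == max(0, L - k + 1)


class TestSequenceSimilarity:
    def test_identical_nonzero_is_one(self):
        v = _vec([2, 1, 0])
        assert sequence_similarity(v, v) == 1.0

    def test_disjoint_support_is_zero(self):
        assert sequence_similarity(_vec([1, 0]), _vec([0, 3])) == 0.0

    def test_hand_value(self):
        assert sequence_similarity(_vec([2, 1, 0]), _vec([1, 1, 1])) == pytest.approx(0.6)

    def test_both_zero_defined_as_zero(self):
        assert sequence_similarity(_vec([0, 0]), _vec([0, 0])) == 0.0

    @given(
        st.lists(st.integers(0, 20), min_size=4, max_size=4),
        st.lists(st.integers(0, 20), min_size=4, max_size=4),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_one_iff_identical(self, a, b):
        va, vb = _vec(a), _vec(b)
        s = sequence_similarity(va, vb)
        assert 0.0 <= s <= 1.0
        if a == b and sum(a) > 0:
            assert s == pytest.approx(1.0)
        elif a != b:
            assert s < 1.0

    def test_matrix_diagonal_and_symmetry(self):
        seqs = {"a": "ACGUACGU", "b": "UUUGGGCA", "c": "ACGUACGA"}
        S = sequence_similarity_matrix(seqs, ["a", "b", "c"], k=3)
        assert np.allclose(np.diag(S.values), 1.0)
        assert np.allclose(S.values, S.values.T)


class TestGipk:
    def test_bandwidth_identity_2x2(self):
        A = AssociationMatrix(np.eye(2, dtype=int), ["m0", "m1"], ["d0", "d1"])
        assert gipk_bandwidth(A, "mirna").lambda_value == pytest.approx(1.0)

    def test_bandwidth_all_ones(self):
        A = AssociationMatrix(np.ones((3, 4), dtype=int), list("abc"), list("wxyz"))
        assert gipk_bandwidth(A, "mirna").lambda_value == pytest.approx(1 / 4)
        assert gipk_bandwidth(A, "disease").lambda_value == pytest.approx(1 / 3)

    def test_all_zero_profiles_error(self):
        with pytest.raises(ValueError, match="empty interaction profile"):
            gipk_bandwidth(
                AssociationMatrix(np.zeros((2, 2), dtype=int), ["a", "b"], ["c", "d"]), "mirna"
            )

    def test_identity_offdiagonal_value(self):
        A = AssociationMatrix(np.eye(2, dtype=int), ["m0", "m1"], ["d0", "d1"])
        S = gipk_similarity(A, "mirna")
        assert S.values[0, 1] == pytest.approx(np.exp(-2.0), abs=1e-12)
        assert S.values[0, 0] == 1.0

    @pytest.mark.parametrize("axis", ["mirna", "disease"])
    def test_matches_brute_force_oracle(self, axis):
        rng = np.random.default_rng(3)
        for trial in range(5):
            vals = (rng.random((10, 10)) < 0.3).astype(int)
            vals[0, 0] = 1  # keep at least one nonzero profile
            A = AssociationMatrix(vals, [f"m{i}" for i in range(10)], [f"d{j}" for j in range(10)])
            S = gipk_similarity(A, axis)
            P = vals.astype(float) if axis == "mirna" else vals.T.astype(float)
            lam = 1.0 / np.mean([p @ p for p in P])
            for i in range(10):
                for j in range(10):
                    expected = np.exp(-lam * np.sum((P[i] - P[j]) ** 2))
                    assert S.values[i, j] == pytest.approx(expected, abs=1e-10)

    def test_permutation_equivariance(self, small_A):
        S = gipk_similarity(small_A, "mirna")
        perm = np.array([3, 1, 5, 0, 4, 2])
        A2 = AssociationMatrix(
            small_A.values[perm], [small_A.mirna_ids[i] for i in perm], small_A.disease_ids
        )
        S2 = gipk_similarity(A2, "mirna")
        np.testing.assert_allclose(S2.values, S.values[np.ix_(perm, perm)], atol=1e-12)

    def test_fuzzed_symmetry_and_range(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            m, n = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            vals = (rng.random((m, n)) < 0.5).astype(int)
            if vals.sum() == 0:
                vals[0, 0] = 1
            A = AssociationMatrix(vals, [f"m{i}" for i in range(m)], [f"d{j}" for j in range(n)])
            S = gipk_similarity(A, "mirna")
            assert np.abs(S.values - S.values.T).max() < 1e-12
            assert S.values.min() >= 0 and S.values.max() <= 1


class TestDagSemantic:
    def test_self_contribution(self, chain_dag):
        assert dag_semantic_contribution(chain_dag, "d")["d"] == 1.0

    def test_chain_decay(self, chain_dag):
        c = dag_semantic_contribution(chain_dag, "d")
        assert c["X"] == pytest.approx(0.5)
        assert c["R"] == pytest.approx(0.25)

    def test_diamond_takes_max_path(self):
        # d -> P1 -> R and d -> R directly: R gets max(0.5, 0.25) = 0.5
        dag = DiseaseDAG(["R", "P1", "d"], [("P1", "R"), ("d", "P1"), ("d", "R")], decay=0.5)
        c = dag_semantic_contribution(dag, "d")
        assert c["R"] == pytest.approx(0.5)

    def test_unknown_id_rejected(self, chain_dag):
        with pytest.raises(KeyError):
            dag_semantic_contribution(chain_dag, "nope")

    def test_identical_disease_similarity_one(self, chain_dag):
        assert dag_semantic_similarity(chain_dag, "d", "d") == pytest.approx(1.0)

    def test_sibling_value(self, chain_dag):
        assert dag_semantic_similarity(chain_dag, "A", "B") == pytest.approx(1 / 3)

    def test_disjoint_roots_zero(self):
        dag = DiseaseDAG(["R1", "R2", "a", "b"], [("a", "R1"), ("b", "R2")])
        assert dag_semantic_similarity(dag, "a", "b") == 0.0

    def test_symmetry_on_random_dag(self):
        rng = np.random.default_rng(5)
        nodes = [f"n{i}" for i in range(20)]
        edges = [(nodes[i], nodes[int(rng.integers(0, i))]) for i in range(1, 20)]
        extra = [(nodes[i], nodes[int(rng.integers(0, i))]) for i in range(5, 20, 4)]
        dag = DiseaseDAG(nodes, edges + extra)
        for _ in range(40):
            a, b = rng.choice(20, 2, replace=False)
            assert dag_semantic_similarity(dag, nodes[a], nodes[b]) == pytest.approx(
                dag_semantic_similarity(dag, nodes[b], nodes[a]), abs=1e-12
            )

    def test_path_product_oracle(self):
        """Contribution equals max over directed paths of decay^length."""
        import itertools
        import networkx as nx

        rng = np.random.default_rng(9)
        nodes = [f"n{i}" for i in range(12)]
        edges = [(nodes[i], nodes[int(rng.integers(0, i))]) for i in range(1, 12)]
        edges += [(nodes[i], nodes[int(rng.integers(0, i))]) for i in range(4, 12, 3)]
        dag = DiseaseDAG(nodes, list(dict.fromkeys(edges)))
        g = nx.DiGraph(dag.parent_edges)
        for d in nodes[5:]:
            contrib = dag_semantic_contribution(dag, d)
            for t, val in contrib.items():
                if t == d:
                    continue
                paths = list(nx.all_simple_paths(g, d, t))
                expected = max(0.5 ** (len(p) - 1) for p in paths)
                assert val == pytest.approx(expected, abs=1e-12)

    def test_matrix_agrees_with_pairwise(self, chain_dag):
        ids = ["d", "A", "B"]
        M = dag_semantic_matrix(chain_dag, ids)
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                assert M.values[i, j] == pytest.approx(dag_semantic_similarity(chain_dag, a, b))


class TestFunctionalSimilarity:
    def test_identical_sets_give_one(self):
        dsim = random_similarity(4, 1, ids=list("wxyz"))
        sets = {"m1": {"w", "x"}, "m2": {"w", "x"}}
        S = functional_similarity(sets, dsim)
        assert S.values[0, 1] == pytest.approx(1.0)

    def test_singleton_sets_reduce_to_pair_similarity(self):
        dsim = random_similarity(4, 2, ids=list("wxyz"))
        S = functional_similarity({"m1": {"w"}, "m2": {"y"}}, dsim)
        assert S.values[0, 1] == pytest.approx(dsim.values[0, 2])

    def test_empty_set_zero_offdiagonal(self):
        dsim = random_similarity(3, 3, ids=list("abc"))
        S = functional_similarity({"m1": set(), "m2": {"a"}}, dsim)
        assert S.values[0, 1] == 0.0
        assert S.values[0, 0] == 1.0

    def test_nested_loop_oracle(self):
        rng = np.random.default_rng(7)
        ids = [f"d{j}" for j in range(10)]
        dsim = random_similarity(10, 4, ids=ids)
        sets = {
            f"m{i}": set(rng.choice(ids, size=int(rng.integers(1, 5)), replace=False))
            for i in range(10)
        }
        S = functional_similarity(sets, dsim)
        idx = dsim.index()
        for a, ma in enumerate(sets):
            for b, mb in enumerate(sets):
                if a == b:
                    continue
                DE1, DE2 = sorted(sets[ma]), sorted(sets[mb])
                tot = sum(max(dsim.values[idx[x], idx[y]] for y in DE2) for x in DE1)
                tot += sum(max(dsim.values[idx[y], idx[x]] for x in DE1) for y in DE2)
                assert S.values[a, b] == pytest.approx(tot / (len(DE1) + len(DE2)), abs=1e-10)

    def test_unknown_disease_rejected(self):
        dsim = random_similarity(2, 5, ids=["a", "b"])
        with pytest.raises(ValueError, match="absent"):
            functional_similarity({"m1": {"zzz"}}, dsim)


class TestIntegration:
    def test_mirna_mean_of_three(self):
        ids = list("abc")
        mk = lambda v, meas: SimilarityMatrix(np.full((3, 3), v) + np.eye(3) * (1 - v), ids, meas)
        out = integrate_mirna_similarity(mk(0.9, "seq"), mk(0.6, "gipk"), mk(0.3, "functional"))
        assert out.values[0, 1] == pytest.approx(0.6)

    def test_disease_mean_of_two(self):
        ids = list("ab")
        a = SimilarityMatrix(np.array([[1, 1.0], [1.0, 1]]), ids, "semantic")
        b = SimilarityMatrix(np.array([[1, 0.5], [0.5, 1]]), ids, "gipk")
        assert integrate_disease_similarity(a, b).values[0, 1] == pytest.approx(0.75)

    def test_idempotent_on_identical(self):
        S = random_similarity(4, 8)
        out = integrate_mirna_similarity(
            SimilarityMatrix(S.values, S.entity_ids, "seq"),
            S,
            SimilarityMatrix(S.values, S.entity_ids, "functional"),
        )
        np.testing.assert_allclose(out.values, S.values)

    def test_id_mismatch_rejected(self):
        a = random_similarity(3, 1, ids=list("abc"))
        b = random_similarity(3, 2, ids=list("abd"))
        with pytest.raises(ValueError, match="mismatch"):
            integrate_disease_similarity(a, b)
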