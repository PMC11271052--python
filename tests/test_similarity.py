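"""Similarity measures against independent oracles and worked examples."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hganlda.similarity import (
    DegenerateInputError,
    DiseaseDAG,
    FusionConfig,
    InvalidDAGError,
    InvalidInputError,
    AlignmentError,
    SequenceRecord,
    SimilarityMatrix,
    disease_semantic_similarity,
    fuse_similarities,
    gip_kernel_similarity,
    lncrna_sequence_similarity,
    weighted_edit_distance,
)

from _oracles import dss_oracle, edit_distance_oracle, gip_oracle

seq_strategy = st.text(alphabet="ACGU", min_size=0, max_size=12)


class TestSequenceSimilarity:
    @given(seq_strategy, seq_strategy)
    def test_matches_dp_oracle(self, a, b):
        assert weighted_edit_distance(a, b) == edit_distance_oracle(a, b)

    @given(seq_strategy, seq_strategy, st.integers(1, 4), st.integers(1, 4))
    def test_matches_dp_oracle_general_costs(self, a, b, sub, indel):
        assert weighted_edit_distance(a, b, sub, indel) == edit_distance_oracle(
            a, b, sub, indel
        )

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGU", "ACGU", 1.0),
            ("ACGU", "ACGA", 0.75),  # one substitution at cost 2, 1 - 2/8
            ("", "AC", 0.0),  # two insertions at cost 1, 1 - 2/2
        ],
    )
    def test_worked_examples(self, a, b, expected):
        sim = lncrna_sequence_similarity(
            [SequenceRecord("x", a), SequenceRecord("y", b)]
        )
        assert sim.values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_unit_diagonal(self, rng):
        seqs = [
            SequenceRecord(f"s{i}", "".join(rng.choice(list("ACGU"), size=8)))
            for i in range(6)
        ]
        sim = lncrna_sequence_similarity(seqs)
        assert np.allclose(sim.values, sim.values.T)
        assert np.allclose(np.diag(sim.values), 1.0)

    def test_two_empty_sequences_error(self):
        with pytest.raises(InvalidInputError, match="empty"):
            lncrna_sequence_similarity(
                [SequenceRecord("a", ""), SequenceRecord("b", "")]
            )

    def test_unusual_characters_warn_but_compute(self):
        with pytest.warns(UserWarning, match="ordinary symbols"):
            sim = lncrna_sequence_similarity(
                [SequenceRecord("a", "ACGN"), SequenceRecord("b", "ACGN")]
            )
        assert sim.values[0, 1] == 1.0

    def test_case_insensitive(self):
        assert weighted_edit_distance("acgu", "ACGU") == 0

    def test_invalid_costs(self):
        with pytest.raises(InvalidInputError):
            weighted_edit_distance("A", "C", sub_cost=0)


def _random_dag(rng, n):
    """Random DAG: each node gets 0-2 parents among earlier nodes."""
    nodes = [f"d{i}" for i in range(n)]
    edges = []
    for i in range(1, n):
        for parent in rng.choice(i, size=min(i, int(rng.integers(0, 3))), replace=False):
            edges.append((nodes[i], nodes[int(parent)]))
    return nodes, edges


class TestDiseaseSemanticSimilarity:
    def test_self_similarity_is_one(self, rng):
        nodes, edges = _random_dag(rng, 8)
        dag = DiseaseDAG(nodes, edges)
        sim = disease_semantic_similarity(dag, nodes)
        assert np.allclose(np.diag(sim.values), 1.0)

    def test_two_node_chain(self):
        dag = DiseaseDAG(["A", "B"], [("B", "A")])
        sim = disease_semantic_similarity(dag, ["A", "B"])
        # T(A)={A}, T(B)={A,B}, D_B(A)=0.5 -> (1+0.5)/(1+1.5)
        assert sim.values[0, 1] == pytest.approx(0.6, abs=1e-12)

    def test_disjoint_components_zero(self):
        dag = DiseaseDAG(["A", "B"], [])
        sim = disease_semantic_similarity(dag, ["A", "B"])
        assert sim.values[0, 1] == 0.0

    def test_matches_path_enumeration_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 16))
            nodes, edges = _random_dag(rng, n)
            dag = DiseaseDAG(nodes, edges)
            parents = {c: [] for c in nodes}
            for c, p in edges:
                parents[c].append(p)
            sim = disease_semantic_similarity(dag, nodes)
            i, j = rng.integers(n), rng.integers(n)
            expected = dss_oracle(parents, nodes[int(i)], nodes[int(j)])
            assert sim.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_cycle_rejected(self):
        with pytest.raises(InvalidDAGError, match="cycle"):
            DiseaseDAG(["A", "B"], [("A", "B"), ("B", "A")])

    def test_unknown_disease_lookup_error(self):
        dag = DiseaseDAG(["A"], [])
        with pytest.raises(LookupError, match="nope"):
            disease_semantic_similarity(dag, ["A", "nope"])

    def test_multiple_parents_take_max_path(self):
        # D has two parents P1, P2; P1 is also parent of P2: two paths to P1,
        # lengths 1 and 2 -> contribution max(0.5, 0.25) = 0.5
        dag = DiseaseDAG(
            ["P1", "P2", "D"], [("D", "P1"), ("D", "P2"), ("P2", "P1")]
        )
        contrib = dag.ancestor_contributions("D")
        assert contrib == {"D": 1.0, "P1": 0.5, "P2": 0.5}


class TestGIPKernel:
    def test_orthogonal_unit_profiles(self):
        sim = gip_kernel_similarity(np.array([[1, 0], [0, 1]]))
        assert sim[0, 1] == pytest.approx(np.exp(-2), abs=1e-12)

    def test_identical_profiles(self):
        sim = gip_kernel_similarity(np.array([[1, 0, 1], [1, 0, 1], [0, 1, 0]]))
        assert sim[0, 1] == pytest.approx(1.0)

    def test_matches_direct_formula(self, rng):
        assoc = (rng.random((7, 9)) < 0.4).astype(int)
        assoc[assoc.sum(axis=1) == 0, 0] = 1
        for orientation, profiles in (("rows", assoc), ("columns", assoc.T)):
            sim = gip_kernel_similarity(assoc, orientation)
            expected = gip_oracle(profiles)
            np.fill_diagonal(expected, 1.0)
            assert np.allclose(sim, expected, atol=1e-12)

    def test_positive_symmetric_unit_diagonal(self, rng):
        assoc = (rng.random((6, 5)) < 0.5).astype(int)
        assoc[0] = 1  # keep at least one nonzero row
        sim = gip_kernel_similarity(assoc)
        assert (sim > 0).all()
        assert np.allclose(sim, sim.T)
        assert np.allclose(np.diag(sim), 1.0)

    def test_profile_permutation_permutes_output(self, rng):
        assoc = (rng.random((6, 8)) < 0.4).astype(int)
        assoc[:, 0] = 1
        perm = rng.permutation(6)
        base = gip_kernel_similarity(assoc)
        permuted = gip_kernel_similarity(assoc[perm])
        assert np.allclose(permuted, base[np.ix_(perm, perm)])

    def test_all_zero_matrix_degenerate(self):
        with pytest.raises(DegenerateInputError):
            gip_kernel_similarity(np.zeros((3, 4)))


class TestFusion:
    def test_alpha_one_halves_first_input(self):
        a = SimilarityMatrix(["x", "y"], np.array([[1.0, 0.4], [0.4, 1.0]]))
        b = SimilarityMatrix(["x", "y"], np.array([[1.0, 0.2], [0.2, 1.0]]))
        fused = fuse_similarities(a, b, FusionConfig(alpha=1.0))
        assert np.allclose(fused.values, a.values / 2)

    def test_worked_example(self):
        a = SimilarityMatrix(["x", "y"], np.array([[1.0, 0.4], [0.4, 1.0]]))
        b = SimilarityMatrix(["x", "y"], np.array([[1.0, 0.2], [0.2, 1.0]]))
        fused = fuse_similarities(a, b, FusionConfig(alpha=0.5))
        assert np.allclose(fused.values, [[0.5, 0.15], [0.15, 0.5]])

    def test_equal_inputs_any_alpha(self):
        a = SimilarityMatrix(["x", "y"], np.array([[1.0, 0.3], [0.3, 1.0]]))
        fused = fuse_similarities(a, a, FusionConfig(alpha=0.5))
        assert np.allclose(fused.values, a.values / 2)

    @given(st.floats(0.01, 1.0), st.floats(0.0, 0.4))
    def test_monotone_in_first_input(self, alpha, bump):
        a = np.array([[1.0, 0.3], [0.3, 1.0]])
        b = np.array([[1.0, 0.5], [0.5, 1.0]])
        lo = fuse_similarities(
            SimilarityMatrix(["x", "y"], a), SimilarityMatrix(["x", "y"], b),
            FusionConfig(alpha=alpha),
        )
        a2 = a.copy()
        a2[0, 1] = a2[1, 0] = a[0, 1] + bump
        hi = fuse_similarities(
            SimilarityMatrix(["x", "y"], a2), SimilarityMatrix(["x", "y"], b),
            FusionConfig(alpha=alpha),
        )
        assert hi.values[0, 1] >= lo.values[0, 1]

    def test_mismatched_node_ids_rejected(self):
        a = SimilarityMatrix(["x", "y"], np.eye(2))
        b = SimilarityMatrix(["x", "z"], np.eye(2))
        with pytest.raises(AlignmentError):
            fuse_similarities(a, b)

    def test_invalid_config(self):
        with pytest.raises(InvalidInputError):
            FusionConfig(alpha=1.5)
        with pytest.raises(InvalidInputError):
            FusionConfig(divisor=0)
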