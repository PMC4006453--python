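"""Jaccard-family similarities, depth weights, network integration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netpropel import (
    Ontology,
    SimilarityNetwork,
    build_similarity_network,
    filter_classes,
    gen_toy_ontology,
    hierarchical_jaccard,
    jaccard,
    leaf_distance_weights,
    propagate_ancestors,
    ua_integrate,
)

sets = st.sets(st.sampled_from([f"t{i}" for i in range(12)]), max_size=8)


class TestJaccard:
    def test_basic_overlap(self):
        assert jaccard({"f1", "f2"}, {"f1", "f3"}) == pytest.approx(1 / 3)

    def test_identical_nonempty_is_one(self):
        assert jaccard({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint_is_zero(self):
        assert jaccard({"a"}, {"b"}) == 0.0

    def test_both_empty_is_zero_by_convention(self):
        assert jaccard(set(), set()) == 0.0


class TestLeafDistanceWeights:
    def test_chain_weights(self):
        ont = Ontology(
            terms={"leaf", "mid", "root"},
            edges=[("leaf", "mid"), ("mid", "root")],
        )
        w = leaf_distance_weights(ont)
        assert w == {"leaf": 1.0, "mid": 0.5, "root": pytest.approx(1 / 3)}

    def test_parent_above_leaf_is_half(self):
        ont = Ontology(terms={"l", "p"}, edges=[("l", "p")])
        w = leaf_distance_weights(ont)
        assert w["l"] == 1.0 and w["p"] == 0.5

    def test_minimum_over_descendant_leaves(self):
        # root has a leaf child and a deep branch: distance is the minimum
        ont = Ontology(
            terms={"root", "shallow", "a", "b"},
            edges=[("shallow", "root"), ("a", "b"), ("b", "root")],
        )
        assert leaf_distance_weights(ont)["root"] == 0.5

    def test_cycle_rejected(self):
        ont = Ontology(terms={"x", "y"}, edges=[("x", "y"), ("y", "x")])
        with pytest.raises(ValueError, match="cycle"):
            leaf_distance_weights(ont)

    @pytest.mark.parametrize("depth,branching", [(0, 1), (2, 2), (3, 3)])
    def test_generated_trees_match_level_formula(self, depth, branching):
        ont, expected = gen_toy_ontology(depth, branching)
        assert leaf_distance_weights(ont) == pytest.approx(expected)


class TestHierarchicalJaccard:
    def test_hand_computed_weighted_value(self):
        w = {"leaf": 1.0, "parent": 0.5}
        assert hierarchical_jaccard(
            {"leaf"}, {"leaf", "parent"}, w
        ) == pytest.approx(2 / 3)

    def test_unknown_term_rejected(self):
        with pytest.raises(KeyError):
            hierarchical_jaccard({"a"}, {"b"}, {"a": 1.0})

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(a=sets, b=sets)
    def test_uniform_weights_reduce_to_classical(self, a, b):
        w = {f"t{i}": 1.0 for i in range(12)}
        assert hierarchical_jaccard(a, b, w) == pytest.approx(jaccard(a, b))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(a=sets, b=sets)
    def test_symmetric_and_bounded(self, b, a):
        w = {f"t{i}": 1.0 / (i + 1) for i in range(12)}
        v = hierarchical_jaccard(a, b, w)
        assert v == pytest.approx(hierarchical_jaccard(b, a, w))
        assert 0.0 <= v <= 1.0


class TestBuildSimilarityNetwork:
    def test_disjoint_profiles_give_empty_network(self):
        net = build_similarity_network(
            {"a": {"f1"}, "b": {"f2"}, "c": {"f3"}}
        )
        assert net.n_edges == 0 and net.nodes == {"a", "b", "c"}

    def test_identical_profiles_give_unit_edge(self):
        net = build_similarity_network({"a": {"f1", "f2"}, "b": {"f1", "f2"}})
        assert net.get("a", "b") == 1.0

    def test_hierarchical_requires_weights(self):
        with pytest.raises(ValueError, match="weights"):
            build_similarity_network(
                {"a": {"t"}, "b": {"t"}}, measure="hierarchical"
            )

    def test_matches_all_pairs_brute_force(self, rng):
        profiles = {
            f"p{i}": {
                f"f{k}" for k in rng.choice(20, size=rng.integers(0, 8),
                                            replace=False)
            }
            for i in range(30)
        }
        net = build_similarity_network(profiles)
        names = sorted(profiles)
        for ai, a in enumerate(names):
            for b in names[ai + 1:]:
                assert net.get(a, b) == pytest.approx(
                    jaccard(profiles[a], profiles[b])
                )


class TestUaIntegrate:
    def test_single_network_is_identity(self):
        net = SimilarityNetwork()
        net.set_edge("a", "b", 0.7)
        out = ua_integrate([net])
        assert out.get("a", "b") == pytest.approx(0.7)

    def test_missing_pair_counts_as_zero(self):
        n1 = SimilarityNetwork()
        n1.set_edge("a", "b", 0.8)
        n2 = SimilarityNetwork()
        n2.set_edge("a", "c", 0.6)
        out = ua_integrate([n1, n2])
        assert out.get("a", "b") == pytest.approx(0.4)
        assert out.get("a", "c") == pytest.approx(0.3)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            ua_integrate([])

    def test_matches_dense_elementwise_mean(self, rng):
        names = [f"p{i}" for i in range(15)]
        nets, dense = [], []
        for _ in range(5):
            net = SimilarityNetwork(nodes=set(names))
            mat = np.zeros((15, 15))
            for _ in range(25):
                i, j = rng.choice(15, size=2, replace=False)
                w = float(rng.random())
                net.set_edge(names[i], names[j], w)
                mat[min(i, j), max(i, j)] = net.get(names[i], names[j])
            nets.append(net)
            dense.append(mat)
        out = ua_integrate(nets)
        mean = np.mean(dense, axis=0)
        for i in range(15):
            for j in range(i + 1, 15):
                assert out.get(names[i], names[j]) == pytest.approx(
                    mean[i, j], abs=1e-15
                )

    def test_bounded_by_max_input_weight(self, rng):
        n1 = SimilarityNetwork()
        n1.set_edge("a", "b", 0.9)
        n2 = SimilarityNetwork()
        n2.set_edge("a", "b", 0.3)
        out = ua_integrate([n1, n2])
        assert out.get("a", "b") <= 0.9


class TestAnnotations:
    def test_filter_boundary_at_threshold(self):
        ann = {f"p{i}": {"t_small" if i < 19 else "t_big"} for i in range(60)}
        for p in range(20):
            ann[f"q{p}"] = {"t_exact"}
        kept = filter_classes(ann, 20)
        assert "t_exact" in kept and "t_small" not in kept

    def test_upper_bound_filter(self):
        ann = {f"p{i}": {"t"} for i in range(30)}
        assert filter_classes(ann, 20, max_positives=25) == []
        assert filter_classes(ann, 20, max_positives=30) == ["t"]

    def test_matches_brute_force_count(self, rng):
        ann = {
            f"p{i}": {f"t{t}" for t in rng.choice(6, size=rng.integers(1, 4),
                                                  replace=False)}
            for i in range(50)
        }
        counts = {}
        for terms in ann.values():
            for t in terms:
                counts[t] = counts.get(t, 0) + 1
        for thr in (1, 5, 10, 20):
            assert filter_classes(ann, thr) == sorted(
                t for t, c in counts.items() if c >= thr
            )

    def test_ancestor_propagation_closure(self):
        ont, _ = gen_toy_ontology(2, 2)
        ann = {"p": {"T.0.1"}}
        closed = propagate_ancestors(ann, ont)
        assert closed["p"] == {"T.0.1", "T.0", "T"}
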