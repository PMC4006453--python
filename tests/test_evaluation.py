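"""Cross-validation, ranking metrics, paired Wilcoxon comparison."""

import numpy as np
import pytest

from netpropel import (
    SyntheticSpec,
    auc,
    compare_paired,
    cross_validate_term,
    gen_planted_partition,
    precision_at_recall,
    stratified_kfold,
)
from helpers import brute_auc, brute_precision_at_recall, brute_wilcoxon_p


class TestStratifiedKfold:
    def test_equal_positive_counts_per_fold(self):
        labels = np.array([1] * 20 + [0] * 80)
        folds = stratified_kfold(labels, 5, rng_seed=0)
        for f in range(5):
            assert np.sum(labels[folds == f]) == 4

    def test_counts_differ_by_at_most_one(self, rng):
        for _ in range(10):
            labels = rng.random(97) < 0.3
            if labels.sum() < 5 or (~labels).sum() < 5:
                continue
            folds = stratified_kfold(labels, 5, rng_seed=3)
            for cls in (True, False):
                counts = [np.sum(labels[folds == f] == cls) for f in range(5)]
                assert max(counts) - min(counts) <= 1

    def test_deterministic_given_seed(self):
        labels = np.array([1] * 10 + [0] * 40)
        a = stratified_kfold(labels, 5, rng_seed=9)
        b = stratified_kfold(labels, 5, rng_seed=9)
        assert np.array_equal(a, b)

    def test_too_few_positives_rejected(self):
        labels = np.array([1] * 3 + [0] * 50)
        with pytest.raises(ValueError):
            stratified_kfold(labels, 5, rng_seed=0)


class TestAuc:
    def test_perfect_separation(self):
        assert auc(np.array([0.9, 0.8, 0.1, 0.2]),
                   np.array([1, 1, 0, 0])) == 1.0

    def test_all_tied_scores_give_half(self):
        assert auc(np.ones(10), np.array([1] * 3 + [0] * 7)) == 0.5

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError):
            auc(np.array([1.0, 2.0]), np.array([1, 1]))

    def test_matches_brute_force_pair_counting(self, rng):
        for _ in range(20):
            scores = rng.integers(0, 6, size=40).astype(float)  # ties likely
            labels = rng.random(40) < 0.4
            if labels.sum() in (0, 40):
                continue
            assert auc(scores, labels) == pytest.approx(
                brute_auc(scores, labels)
            )

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(10):
            scores = rng.random(60)
            labels = rng.random(60) < 0.3
            if labels.sum() in (0, 60):
                continue
            assert auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores)
            )

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(50)
        labels = rng.random(50) < 0.5
        assert auc(scores, labels) == pytest.approx(
            auc(np.exp(3 * scores), labels)
        )


class TestPrecisionAtRecall:
    def test_first_hit_reaches_half_recall(self):
        scores = np.array([10, 5, 4, 3, 2, 1, 0.9, 0.8, 0.7, 0.6])
        labels = np.zeros(10, dtype=bool)
        labels[[0, 3]] = True  # ranks 1 and 4
        assert precision_at_recall(scores, labels, 0.5) == 1.0
        assert precision_at_recall(scores, labels, 1.0) == 0.5

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            precision_at_recall(np.ones(4), np.zeros(4), 0.2)

    def test_matches_exhaustive_cutoff_enumeration(self, rng):
        for _ in range(30):
            scores = rng.integers(0, 5, size=25).astype(float)
            labels = rng.random(25) < 0.3
            if labels.sum() == 0:
                continue
            for r in (0.2, 0.4, 0.75, 1.0):
                assert precision_at_recall(scores, labels, r) == pytest.approx(
                    brute_precision_at_recall(scores, labels, r)
                )


class TestComparePaired:
    def test_identical_vectors_not_significant(self):
        stat, p, sig = compare_paired([0.5] * 10, [0.5] * 10)
        assert p == 1.0 and not sig

    def test_uniform_shift_significant(self):
        a = np.linspace(0.1, 0.9, 30)
        stat, p, sig = compare_paired(a, a + 0.05, alpha=0.01)
        assert stat == 0.0 and sig

    def test_exact_p_matches_exhaustive_enumeration(self, rng):
        for _ in range(15):
            m = int(rng.integers(4, 12))
            d = np.round(rng.normal(size=m), 2)
            _, p, _ = compare_paired(np.zeros(m), d)
            assert p == pytest.approx(brute_wilcoxon_p(d))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_paired([1.0, 2.0], [1.0])

    def test_normal_approximation_branch_reasonable(self, rng):
        # large-m branch must broadly agree with scipy's implementation
        from scipy.stats import wilcoxon

        a = rng.random(40)
        b = a + rng.normal(0.05, 0.1, size=40)
        _, p, _ = compare_paired(a, b)
        ref = wilcoxon(b - a, correction=True, method="approx").pvalue
        assert p == pytest.approx(ref, rel=0.05)


@pytest.fixture(scope="module")
def fixture():
    graph, labels = gen_planted_partition(SyntheticSpec())
    annotations = {
        graph.accessions[i]: {f"GO:MOD{labels[i]}"}
        for i in range(graph.n)
    }
    return graph, annotations


class TestCrossValidateTerm:

    def test_planted_signal_recovered(self, fixture):
        graph, annotations = fixture
        ev = cross_validate_term(graph, annotations, "GO:MOD0",
                                 rng_seed=0)
        assert ev.auc > 0.9
        assert ev.n_pos == 20

    def test_deterministic_given_seed(self, fixture):
        graph, annotations = fixture
        a = cross_validate_term(graph, annotations, "GO:MOD1", rng_seed=7)
        b = cross_validate_term(graph, annotations, "GO:MOD1", rng_seed=7)
        assert a == b

    def test_all_positive_term_rejected(self, fixture):
        graph, _ = fixture
        annotations = {acc: {"GO:ALL"} for acc in graph.accessions}
        with pytest.raises(ValueError, match="negatives"):
            cross_validate_term(graph, annotations, "GO:ALL")

    def test_seeds_exclude_held_out_fold(self, fixture):
        graph, annotations = fixture
        ev = cross_validate_term(graph, annotations, "GO:MOD0", rng_seed=1)
        positives = {
            acc for acc, t in annotations.items() if "GO:MOD0" in t
        }
        for seeds in ev.fold_seeds:
            assert len(seeds) == 16  # 4/5 of 20 positives
            assert set(seeds) <= positives

    def test_eval_vertex_restriction(self, fixture):
        graph, annotations = fixture
        sub = list(range(0, 40))
        ev = cross_validate_term(
            graph, annotations, "GO:MOD0", rng_seed=2, eval_vertices=sub
        )
        assert 0.0 <= ev.auc <= 1.0
        assert ev.n_pos == 20  # module 0 lies inside the subset
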