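"""Semantic-similarity redundancy scoring."""

import math

import numpy as np
import pytest

from netenrich import (
    AnnotationSet,
    InformationContentSimilarity,
    OntologyDag,
    ass,
    background_distribution,
    compare_method_redundancy,
    pairwise_similarity,
)
from netenrich.redundancy import matrix_score_fn


@pytest.fixture
def chain_dag():
    """root -> a -> b with annotation counts {root: 4, a: 2, b: 1}."""
    dag = OntologyDag({"root": [], "a": ["root"], "b": ["a"]})
    annotation = AnnotationSet(
        {
            "root": ["g1", "g2", "g3", "g4"],
            "a": ["g1", "g2"],
            "b": ["g1"],
        }
    )
    return dag, annotation


@pytest.fixture
def tree_dag():
    """Two sibling leaves under one parent, two leaves in a disjoint branch."""
    dag = OntologyDag(
        {
            "root": [],
            "left": ["root"],
            "right": ["root"],
            "l1": ["left"],
            "l2": ["left"],
            "r1": ["right"],
            "r2": ["right"],
        }
    )
    annotation = AnnotationSet(
        {
            "l1": ["g1"],
            "l2": ["g2"],
            "r1": ["g3"],
            "r2": ["g4"],
            "left": ["g1", "g2"],
            "right": ["g3", "g4"],
        }
    )
    return dag, annotation


class TestOntologyDag:
    def test_cycle_rejected(self):
        with pytest.raises(Exception):
            OntologyDag({"a": ["b"], "b": ["a"]})

    def test_unknown_parent_rejected(self):
        with pytest.raises(ValueError, match="parent"):
            OntologyDag({"a": ["ghost"]})

    def test_ancestors_inclusive(self, chain_dag):
        dag, _ = chain_dag
        assert dag.ancestors("b") == {"b", "a", "root"}
        assert dag.roots() == ["root"]

    def test_from_obo(self, tmp_path):
        obo = tmp_path / "mini.obo"
        obo.write_text(
            "format-version: 1.2\n\n"
            "[Term]\nid: X:0\nname: root\nnamespace: test\n\n"
            "[Term]\nid: X:1\nname: child\nnamespace: test\nis_a: X:0 ! root\n"
        )
        dag = OntologyDag.from_obo(str(obo))
        assert dag.parents("X:1") == ("X:0",)
        assert dag.namespaces["X:1"] == "test"


class TestInformationContentSimilarity:
    def test_lin_self_similarity_is_one(self, chain_dag):
        dag, ann = chain_dag
        sim = InformationContentSimilarity(dag, ann, method="lin")
        assert sim("b", "b") == pytest.approx(1.0)

    def test_root_only_common_ancestor_scores_zero(self, tree_dag):
        dag, ann = tree_dag
        sim = InformationContentSimilarity(dag, ann, method="lin")
        assert sim("l1", "r1") == 0.0

    def test_chain_hand_computed_lin(self, chain_dag):
        """lin(a, b) = 2 IC(a) / (IC(a) + IC(b)) with IC = -log(count/4)."""
        dag, ann = chain_dag
        sim = InformationContentSimilarity(dag, ann, method="lin")
        ic_a = -math.log(2 / 4)
        ic_b = -math.log(1 / 4)
        assert sim("a", "b") == pytest.approx(2 * ic_a / (ic_a + ic_b), abs=1e-12)

    def test_resnik_normalised_bounded(self, chain_dag):
        dag, ann = chain_dag
        sim = InformationContentSimilarity(dag, ann, method="resnik_normalized")
        assert 0.0 <= sim("a", "b") <= 1.0
        assert sim("b", "b") == pytest.approx(1.0)  # b has the max IC

    def test_symmetry(self, tree_dag):
        dag, ann = tree_dag
        sim = InformationContentSimilarity(dag, ann, method="lin")
        assert sim("l1", "l2") == sim("l2", "l1")

    def test_unannotated_term_errors(self, chain_dag):
        dag, _ = chain_dag
        ann = AnnotationSet({"a": ["g1"]})
        sim = InformationContentSimilarity(dag, ann)
        with pytest.raises(ValueError, match="undefined"):
            sim.ic("b")

    def test_term_absent_from_dag_errors(self, chain_dag):
        dag, ann = chain_dag
        with pytest.raises(KeyError):
            pairwise_similarity("a", "nope", dag, ann)


class TestAss:
    def test_single_pair(self):
        assert ass({"a", "b"}, lambda x, y: 0.4) == pytest.approx(0.4)

    def test_three_term_mean(self):
        scores = {
            frozenset({"a", "b"}): 0.2,
            frozenset({"a", "c"}): 0.4,
            frozenset({"b", "c"}): 0.6,
        }
        fn = lambda x, y: scores[frozenset({x, y})]
        assert ass(["a", "b", "c"], fn) == pytest.approx(0.4)

    def test_permutation_invariant(self, tree_dag):
        dag, ann = tree_dag
        sim = InformationContentSimilarity(dag, ann)
        assert ass(["l1", "l2", "r1"], sim) == pytest.approx(
            ass(["r1", "l1", "l2"], sim)
        )

    def test_too_small_set_errors(self):
        with pytest.raises(ValueError, match=">= 2"):
            ass({"a"}, lambda x, y: 1.0)

    def test_upper_bound_one(self):
        assert ass(["a", "b", "c"], lambda x, y: 1.0) == pytest.approx(1.0)

    def test_matrix_score_fn_symmetric_lookup(self):
        fn = matrix_score_fn({("a", "b"): 0.3})
        assert fn("b", "a") == 0.3


class TestBackgroundDistribution:
    def test_sample_count_and_percentile_bounds(self, tree_dag):
        dag, ann = tree_dag
        sim = InformationContentSimilarity(dag, ann)
        rep = background_distribution(
            2, ann, dag, sim, repetitions=200, rng=np.random.default_rng(0),
            observed=0.5,
        )
        assert len(rep.background_samples) == 200
        assert 0.0 <= rep.percentile <= 100.0

    def test_degenerate_all_equal_gives_midrank_fifty(self):
        ann = AnnotationSet({"a": ["g1"], "b": ["g2"], "c": ["g3"]})
        rep = background_distribution(
            2, ann, None, lambda x, y: 0.0, repetitions=50,
            rng=np.random.default_rng(1), observed=0.0,
        )
        assert rep.percentile == pytest.approx(50.0)

    def test_insufficient_terms_error(self, tree_dag):
        dag, ann = tree_dag
        sim = InformationContentSimilarity(dag, ann)
        with pytest.raises(ValueError, match="sample sets of size"):
            background_distribution(100, ann, dag, sim, repetitions=1)

    def test_background_mean_stable_across_seeds(self, tree_dag):
        """Two independent resamples agree within 3 pooled standard errors."""
        dag, ann = tree_dag
        sim = InformationContentSimilarity(dag, ann)
        reps = 2000
        a = background_distribution(
            2, ann, dag, sim, repetitions=reps, rng=np.random.default_rng(10)
        ).background_samples
        b = background_distribution(
            2, ann, dag, sim, repetitions=reps, rng=np.random.default_rng(11)
        ).background_samples
        se = np.sqrt(a.var(ddof=1) / reps + b.var(ddof=1) / reps)
        assert abs(a.mean() - b.mean()) <= 3 * se


class TestCompareMethodRedundancy:
    def test_sibling_set_more_redundant_than_disjoint(self, tree_dag):
        dag, ann = tree_dag
        sim = InformationContentSimilarity(dag, ann)
        reports = compare_method_redundancy(
            {"siblings": ["l1", "l2"], "disjoint": ["l1", "r1"]},
            ann, dag, sim, repetitions=100, rng=np.random.default_rng(2),
        )
        assert reports["siblings"].observed_ass > reports["disjoint"].observed_ass

    def test_identical_sets_identical_scores(self, tree_dag):
        dag, ann = tree_dag
        sim = InformationContentSimilarity(dag, ann)
        reports = compare_method_redundancy(
            {"m1": ["l1", "l2"], "m2": ["l2", "l1"]},
            ann, dag, sim, repetitions=50, rng=np.random.default_rng(3),
        )
        assert reports["m1"].observed_ass == reports["m2"].observed_ass
        # shared background of matching size
        np.testing.assert_array_equal(
            reports["m1"].background_samples, reports["m2"].background_samples
        )

    def test_singleton_set_rejected(self, tree_dag):
        dag, ann = tree_dag
        sim = InformationContentSimilarity(dag, ann)
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_method_redundancy({"m": ["l1"]}, ann, dag, sim, 10)
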