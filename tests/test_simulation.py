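"""Synthetic worlds, active-list generation and the benchmark engine."""

import numpy as np
import pytest

from netenrich import (
    GENERATING_PRESETS,
    AnnotationSet,
    GeneNetwork,
    ModelParams,
    SimulationSpec,
    build_universe,
    classify_genes,
    generate_active_genes,
    make_synthetic_world,
    run_simulation_study,
    subsample_annotation,
)
from netenrich.core import ActiveGeneList


class TestMakeSyntheticWorld:
    def test_reproducible_from_seed(self):
        a = make_synthetic_world(n_genes=60, n_terms=12, seed=3)
        b = make_synthetic_world(n_genes=60, n_terms=12, seed=3)
        assert a.annotation.gene_sets() == b.annotation.gene_sets()
        assert a.network.edges() == b.network.edges()

    def test_zero_density_gives_edgeless_network(self):
        w = make_synthetic_world(n_genes=40, n_terms=5, density_param=0.0, seed=0)
        assert w.network.n_edges == 0

    def test_no_terms_is_an_error(self):
        with pytest.raises(ValueError):
            make_synthetic_world(n_terms=0)

    def test_oversized_terms_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_synthetic_world(n_genes=10, term_size_dist=(5, 20))

    def test_preferential_attachment_model(self):
        w = make_synthetic_world(
            n_genes=50, n_terms=5, network_model="preferential_attachment",
            density_param=2, seed=1,
        )
        assert w.network.n_edges > 0


class TestSubsampleAnnotation:
    def test_size_filter_semantics(self):
        full = AnnotationSet(
            {"tiny": ["g1"], "ok": ["g1", "g2", "g3"], "huge": [f"g{i}" for i in range(600)]}
        )
        rng = np.random.default_rng(0)
        sub = subsample_annotation(full, (2, 500), 1, rng)
        assert sub.term_ids == ["ok"]

    def test_all_eligible_terms_returned(self):
        full = AnnotationSet({f"T{i}": [f"g{i}", f"g{i+1}"] for i in range(5)})
        rng = np.random.default_rng(1)
        sub = subsample_annotation(full, (1, 10), 5, rng)
        assert set(sub.term_ids) == set(full.term_ids)

    def test_insufficient_terms_error_states_count(self):
        full = AnnotationSet({"T1": ["g1", "g2"]})
        with pytest.raises(ValueError, match="only 1 terms"):
            subsample_annotation(full, (2, 500), 5, np.random.default_rng(0))

    def test_deterministic_given_seed(self):
        w = make_synthetic_world(n_genes=80, n_terms=30, seed=2)
        a = subsample_annotation(w.annotation, (2, 500), 10, np.random.default_rng(9))
        b = subsample_annotation(w.annotation, (2, 500), 10, np.random.default_rng(9))
        assert a.term_ids == b.term_ids


class TestGenerateActiveGenes:
    def test_degenerate_params_give_core_exactly(self):
        w = make_synthetic_world(n_genes=60, n_terms=10, seed=4)
        rng = np.random.default_rng(0)
        targets = set(w.annotation.term_ids[:2])
        active = generate_active_genes(
            targets, w.annotation, w.network, ModelParams(1.0, 0.0, 0.0, 3.0), rng
        )
        universe = build_universe(w.annotation, w.network)
        cls = classify_genes(
            targets, w.annotation, w.network,
            ActiveGeneList([universe.gene_ids[0]], universe), universe,
        )
        assert active.gene_ids == cls.core_genes

    def test_all_zero_probabilities_rejected(self):
        w = make_synthetic_world(n_genes=30, n_terms=4, term_size_dist=(3, 8), seed=5)
        with pytest.raises(RuntimeError, match="empty"):
            generate_active_genes(
                {w.annotation.term_ids[0]},
                w.annotation,
                w.network,
                ModelParams(0.0, 0.0, 0.0, 3.0),
                np.random.default_rng(0),
            )

    def test_activation_frequencies_match_binomial_expectation(self):
        """Means over repeated draws sit within 3 SE of p1/p2/q per class."""
        w = make_synthetic_world(
            n_genes=300, n_terms=15, term_size_dist=(5, 20), density_param=4.0, seed=6
        )
        params = ModelParams(0.8, 0.3, 0.01, 3.0)
        universe = build_universe(w.annotation, w.network)
        targets = set(w.annotation.term_ids[:3])
        cls = classify_genes(
            targets, w.annotation, w.network,
            ActiveGeneList([universe.gene_ids[0]], universe), universe,
        )
        rng = np.random.default_rng(7)
        n_draws = 2000
        counts = {"core": 0, "peripheral": 0, "other": 0}
        for _ in range(n_draws):
            active = generate_active_genes(
                targets, w.annotation, w.network, params, rng
            )
            counts["core"] += len(active.gene_ids & cls.core_genes)
            counts["peripheral"] += len(active.gene_ids & cls.peripheral_genes)
            counts["other"] += len(active.gene_ids & cls.other_genes)
        for name, group, p in [
            ("core", cls.core_genes, params.p1),
            ("peripheral", cls.peripheral_genes, params.p2),
            ("other", cls.other_genes, params.q),
        ]:
            trials = n_draws * len(group)
            freq = counts[name] / trials
            se = np.sqrt(p * (1 - p) / trials)
            assert abs(freq - p) <= 3 * se, (name, freq, p)


class TestRunSimulationStudy:
    def test_single_run_bookkeeping(self):
        w = make_synthetic_world(n_genes=100, n_terms=25, seed=8)
        spec = SimulationSpec(
            generating_params=GENERATING_PRESETS["group-i"],
            n_annotation_sets=1,
            terms_per_set=20,
            targets_per_set=1,
            active_terms_per_target=3,
            rng_seed=1,
        )
        result = run_simulation_study(w, spec, methods=("network", "fisher_single_term"))
        assert set(result.runs) == {"network", "fisher_single_term"}
        assert all(len(v) == 1 for v in result.runs.values())
        # fisher scores every term of the subsample
        scores, true, all_terms = result.runs["fisher_single_term"][0]
        assert set(scores) == set(all_terms)
        assert len(all_terms) == 20 and len(true) == 3

    def test_reproducible_from_seed(self):
        w = make_synthetic_world(n_genes=100, n_terms=25, seed=8)
        spec = SimulationSpec(
            generating_params=GENERATING_PRESETS["group-i"],
            n_annotation_sets=1,
            terms_per_set=15,
            targets_per_set=2,
            rng_seed=42,
        )
        r1 = run_simulation_study(w, spec, methods=("network",))
        r2 = run_simulation_study(w, spec, methods=("network",))
        assert r1.runs["network"][0][0] == r2.runs["network"][0][0]
        np.testing.assert_array_equal(
            r1.curves["network"].precision, r2.curves["network"].precision
        )

    def test_presets_match_stated_groups(self):
        assert GENERATING_PRESETS["group-i"] == ModelParams(0.8, 0.3, 0.001, 3.0)
        assert GENERATING_PRESETS["group-ii"] == ModelParams(0.5, 0.3, 0.001, 3.0)
        assert GENERATING_PRESETS["group-iii"] == ModelParams(0.8, 0.1, 0.001, 3.0)
        assert GENERATING_PRESETS["group-iv"] == ModelParams(0.8, 0.3, 0.01, 3.0)

    def test_generated_genes_stay_in_universe(self):
        w = make_synthetic_world(n_genes=80, n_terms=20, seed=9)
        universe = build_universe(w.annotation, w.network)
        rng = np.random.default_rng(3)
        active = generate_active_genes(
            set(w.annotation.term_ids[:2]), w.annotation, w.network,
            ModelParams(0.8, 0.3, 0.01, 3.0), rng,
        )
        assert all(g in universe for g in active.gene_ids)
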