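"""Evaluation metrics: error rate, enrichment, survival, AUC."""

import numpy as np
import pytest

import gcna_kpca as gk
from gcna_kpca.evaluation import (
    biological_significance,
    error_rate,
    fisher_enrichment,
    gene_auc,
    logrank_by_median,
    prognostic_significance,
)
from conftest import (
    auc_by_pair_counting,
    hypergeom_tail_by_sum,
    logrank_by_hand,
    make_expr,
    make_groups,
)


def _orthogonal_block_expr(rng, genes_per_block=5, n_samples=16):
    """Two noise-free rank-1 blocks driven by orthogonal factors."""
    f0 = rng.standard_normal(n_samples)
    f0 -= f0.mean()
    f1 = rng.standard_normal(n_samples)
    f1 -= f1.mean() + (np.dot(f1 - f1.mean(), f0) / np.dot(f0, f0)) * f0
    scales = rng.uniform(0.5, 2.0, size=genes_per_block)
    rows = [s * f0 for s in scales] + [s * f1 for s in scales]
    expr = make_expr(np.vstack(rows))
    labels = {g: (0 if i < genes_per_block else 1) for i, g in enumerate(expr.gene_ids)}
    return expr, labels


class TestErrorRate:
    def test_single_module_is_vacuously_zero(self, rng):
        expr = make_expr(rng.standard_normal((4, 6)))
        part = gk.ModulePartition(labels={g: 0 for g in expr.gene_ids}, n_modules=1)
        with pytest.warns(UserWarning):
            assert error_rate(part, expr).error_rate == 0.0

    def test_orthogonal_planted_blocks_have_zero_error(self, rng):
        expr, labels = _orthogonal_block_expr(rng)
        part = gk.ModulePartition(labels=labels, n_modules=2)
        rep = error_rate(part, expr)
        assert rep.error_rate == 0.0
        assert all(mm == pytest.approx(1.0, abs=1e-9) for mm in rep.module_membership.values())

    def test_mislabeled_gene_is_flagged(self, rng):
        expr, labels = _orthogonal_block_expr(rng)
        labels["g0"] = 1  # move one block-0 gene into module 1
        part = gk.ModulePartition(labels=labels, n_modules=2)
        rep = error_rate(part, expr)
        assert rep.violations["g0"]
        assert rep.error_rate == pytest.approx(1 / expr.n_genes)

    def test_invariant_under_relabeling_and_reordering(self, rng):
        expr, _, _ = gk.simulate_expression(gk.SimulationSpec(seed=8, n_background_genes=10))
        part, _ = gk.run_gcna_kpca(expr)
        base = error_rate(part, expr).error_rate
        k = part.n_modules
        swapped = gk.ModulePartition(
            labels={g: (k - 1 - m) for g, m in part.labels.items()}, n_modules=k
        )
        shuffled = expr.subset_genes(list(reversed(expr.gene_ids)))
        assert error_rate(swapped, expr).error_rate == pytest.approx(base, abs=1e-12)
        assert error_rate(part, shuffled).error_rate == pytest.approx(base, abs=1e-12)


class TestFisherEnrichment:
    def test_term_covering_background_is_unenriched(self):
        bg = {f"g{i}" for i in range(50)}
        module = {f"g{i}" for i in range(10)}
        sets = gk.AnnotationSets({"T": ("all", frozenset(bg))})
        [(_, overlap, p)] = fisher_enrichment(module, sets, bg)
        assert overlap == 10
        assert p == pytest.approx(1.0)

    def test_matches_hypergeometric_sum_oracle(self):
        bg = {f"g{i}" for i in range(100)}
        term = frozenset(f"g{i}" for i in range(10))
        module = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(50, 55)}
        sets = gk.AnnotationSets({"T": ("d", term)})
        [(_, overlap, p)] = fisher_enrichment(module, sets, bg)
        assert overlap == 5
        assert p == pytest.approx(hypergeom_tail_by_sum(5, 100, 10, 10), rel=1e-12)

    def test_zero_overlap_gives_p_one(self):
        bg = {"a", "b", "c", "d"}
        sets = gk.AnnotationSets({"T": ("d", frozenset({"c", "d"}))})
        [(_, overlap, p)] = fisher_enrichment({"a", "b"}, sets, bg)
        assert overlap == 0
        assert p == 1.0

    def test_all_small_configurations_match_oracle(self):
        # every 2x2 configuration with background <= 60
        for n_bg in (10, 25, 60):
            genes = [f"g{i}" for i in range(n_bg)]
            bg = set(genes)
            for n_term in (1, n_bg // 3, n_bg):
                term = frozenset(genes[:n_term])
                sets = gk.AnnotationSets({"T": ("d", term)})
                for n_mod in (1, n_bg // 4 or 1, n_bg // 2):
                    for shift in (0, n_bg - n_mod):
                        module = set(genes[shift:shift + n_mod])
                        [(_, overlap, p)] = fisher_enrichment(module, sets, bg)
                        oracle = hypergeom_tail_by_sum(overlap, n_bg, n_term, n_mod)
                        if overlap == 0:
                            assert p == 1.0
                        else:
                            assert p == pytest.approx(oracle, abs=1e-12)

    def test_empty_background_rejected(self):
        sets = gk.AnnotationSets({"T": ("d", frozenset({"a"}))})
        with pytest.raises(gk.DataFormatError):
            fisher_enrichment(set(), sets, set())


class TestBiologicalSignificance:
    def _partition(self):
        labels = {f"a{i}": 0 for i in range(5)} | {f"b{i}": 1 for i in range(5)}
        return gk.ModulePartition(labels=labels, n_modules=2)

    def test_sig_arithmetic_from_known_pvalues(self, monkeypatch):
        # Sig_i sums -log10 p over significant terms: p in {0.01, 0.001}
        # gives 5.0; module Sigs {5, 3} average to 4.0.
        part = self._partition()
        sets = gk.AnnotationSets({"T1": ("d", frozenset({"x"}))})

        fake = {
            0: [("T1", 1, 0.01), ("T2", 1, 0.001), ("T3", 0, 0.5)],
            1: [("T1", 1, 0.001)],
        }
        calls = iter([fake[0], fake[1]])
        monkeypatch.setattr(
            "gcna_kpca.evaluation.fisher_enrichment",
            lambda *a, **k: next(calls),
        )
        rep = biological_significance(part, sets)
        assert rep.sig_per_module[0] == pytest.approx(5.0)
        assert rep.sig_per_module[1] == pytest.approx(3.0)
        assert rep.sig == pytest.approx(4.0)

    def test_no_significant_terms_gives_zero(self):
        part = self._partition()
        # decoy term overlapping everything -> p = 1 everywhere
        sets = gk.AnnotationSets({"T": ("d", frozenset(part.gene_ids))})
        rep = biological_significance(part, sets)
        assert rep.sig == 0.0

    def test_planted_terms_beat_permuted_labels(self):
        # planted annotation terms give the true partition higher Sig
        # than a label permutation in nearly every replicate.
        wins = 0
        n_rep = 50
        for seed in range(n_rep):
            spec = gk.SimulationSpec(
                seed=seed, n_modules=3, genes_per_module=12,
                n_background_genes=0, n_tumor=10, n_normal=10,
            )
            _, _, truth = gk.simulate_expression(spec)
            sets = gk.simulate_annotations(truth, seed=seed)
            genes = truth.module_gene_ids()
            part = gk.ModulePartition(labels=dict(truth.module_labels), n_modules=3)
            rng = np.random.default_rng(seed + 1000)
            perm = rng.permutation([truth.module_labels[g] for g in genes])
            shuffled = gk.ModulePartition(
                labels=dict(zip(genes, map(int, perm))), n_modules=3
            )
            if (
                biological_significance(part, sets).sig
                > biological_significance(shuffled, sets).sig
            ):
                wins += 1
        assert wins / n_rep >= 0.95


class TestLogrank:
    def test_identical_curves_give_p_one(self):
        surv = gk.SurvivalTable(
            [f"s{i}" for i in range(6)],
            np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0]),
            np.array([1, 1, 1, 1, 1, 1]),
        )
        x = np.array([0.0, 0.0, 0.0, 10.0, 10.0, 10.0])  # mirror strata
        assert logrank_by_median(x, surv) == pytest.approx(1.0)

    def test_separated_groups_match_hand_formula(self):
        time = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        event = np.ones(6, dtype=int)
        surv = gk.SurvivalTable([f"s{i}" for i in range(6)], time, event)
        x = np.array([9.0, 9.0, 9.0, 1.0, 1.0, 1.0])  # high expr dies early
        p = logrank_by_median(x, surv)
        p_oracle = logrank_by_hand(time, event, (x > np.median(x)).astype(int))
        assert p == pytest.approx(p_oracle, rel=1e-6)
        assert p < 0.05

    def test_all_censored_gives_p_one(self):
        surv = gk.SurvivalTable(
            ["a", "b", "c", "d"], np.array([1.0, 2.0, 3.0, 4.0]), np.zeros(4, dtype=int)
        )
        with pytest.warns(UserWarning):
            assert logrank_by_median(np.array([1.0, 2.0, 3.0, 4.0]), surv) == 1.0

    def test_degenerate_split_gives_p_one(self):
        surv = gk.SurvivalTable(["a", "b"], np.array([1.0, 2.0]), np.array([1, 1]))
        with pytest.warns(UserWarning):
            assert logrank_by_median(np.array([3.0, 3.0]), surv) == 1.0


class TestPrognosticSignificance:
    def test_ten_genes_at_p05(self):
        assert prognostic_significance([0.05] * 10) == pytest.approx(13.0103, abs=1e-4)

    def test_p_one_contributes_zero(self):
        assert prognostic_significance([1.0]) == 0.0

    def test_simple_sum(self):
        assert prognostic_significance([0.01, 0.1]) == pytest.approx(3.0)

    def test_zero_p_is_clipped_finite(self):
        assert np.isfinite(prognostic_significance([0.0]))


class TestGeneAuc:
    def test_perfect_separation(self):
        x = np.array([5.0, 6.0, 7.0, 1.0, 2.0, 3.0])
        groups = make_groups([f"s{i}" for i in range(6)], 3)
        assert gene_auc(x, groups, [f"s{i}" for i in range(6)]) == 1.0

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(20):
            x = rng.integers(0, 6, size=14).astype(float)  # ties included
            ids = [f"s{i}" for i in range(14)]
            groups = make_groups(ids, 7)
            mask = np.array([True] * 7 + [False] * 7)
            assert gene_auc(x, groups, ids) == pytest.approx(
                auc_by_pair_counting(x, mask), abs=1e-12
            )

    def test_all_tied_values_give_half(self):
        ids = [f"s{i}" for i in range(8)]
        groups = make_groups(ids, 4)
        assert gene_auc(np.full(8, 3.0), groups, ids) == 0.5

    def test_missing_class_rejected(self):
        ids = ["s0", "s1"]
        groups = gk.SampleGroups({"s0": "tumor", "s1": "tumor"})
        with pytest.raises(gk.DataFormatError):
            gene_auc(np.array([1.0, 2.0]), groups, ids)
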