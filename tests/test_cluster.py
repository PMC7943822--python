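"""Eigengene computation and the correlation K-means refinement loop."""

import numpy as np
import pytest

import gcna_kpca as gk
from gcna_kpca.cluster import (
    KpcaConfig,
    assign_genes,
    compute_eigengene,
    correlation_distance,
    run_gcna_kpca,
    update_centers,
)
from conftest import make_expr


def _cor(a, b):
    return float(np.corrcoef(a, b)[0, 1])


class TestEigengene:
    def test_identical_genes_give_member_profile(self, rng):
        g = rng.standard_normal(12)
        expr = make_expr(np.tile(g, (5, 1)) * rng.uniform(0.5, 2.0, size=(5, 1)))
        me = compute_eigengene(expr)
        assert abs(_cor(me, g)) == pytest.approx(1.0, abs=1e-10)
        assert np.linalg.norm(me) == pytest.approx(1.0, abs=1e-12)

    def test_single_gene_module(self, rng):
        g = rng.standard_normal(8)
        me = compute_eigengene(make_expr(g[None, :]))
        z = (g - g.mean()) / g.std()
        np.testing.assert_allclose(me, z / np.linalg.norm(z), atol=1e-12)

    def test_mixed_sign_loadings_match_svd_oracle(self, rng):
        # half the genes are g, half are -g: a rank-1 matrix whose first
        # right-singular vector equals +-standardized g.
        g = rng.standard_normal(10)
        expr = make_expr(np.vstack([g, g, -g, -g]))
        me = compute_eigengene(expr)
        assert abs(_cor(me, g)) == pytest.approx(1.0, abs=1e-10)
        # orientation rule is deterministic
        me2 = compute_eigengene(expr)
        np.testing.assert_array_equal(me, me2)

    def test_sign_follows_mean_standardized_profile(self, rng):
        base = rng.standard_normal(20)
        noise = 0.05 * rng.standard_normal((6, 20))
        expr = make_expr(base + noise)
        me = compute_eigengene(expr)
        z = (expr.values - expr.values.mean(1, keepdims=True)) / expr.values.std(1, keepdims=True)
        assert _cor(me, z.mean(axis=0)) > 0

    def test_constant_gene_is_named(self):
        expr = make_expr(np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]), gene_ids=["flat", "ok"])
        with pytest.raises(gk.DataFormatError, match="flat"):
            compute_eigengene(expr)


class TestCorrelationDistance:
    def test_identity_and_negation_both_zero(self, rng):
        g = rng.standard_normal(10)
        assert correlation_distance(g, g) == pytest.approx(0.0, abs=1e-12)
        assert correlation_distance(g, -g) == pytest.approx(0.0, abs=1e-12)

    def test_direct_substitution(self, rng):
        # build a center with cor(g, C) = 0.65 exactly
        g = rng.standard_normal(40)
        h = rng.standard_normal(40)
        zg = (g - g.mean()) / g.std()
        zh = h - h.mean() - (np.dot(h - h.mean(), zg) / 40) * zg
        zh /= zh.std()
        c = 0.65 * zg + np.sqrt(1 - 0.65**2) * zh
        assert correlation_distance(g, c) == pytest.approx(0.35, abs=1e-10)

    def test_constant_vector_rejected(self):
        with pytest.raises(gk.DataFormatError):
            correlation_distance(np.ones(5), np.arange(5.0))


class TestAssignment:
    def test_gene_matching_a_center_gets_its_label(self, rng):
        centers = [c / np.linalg.norm(c) for c in rng.standard_normal((3, 15))]
        expr = make_expr(centers[2][None, :] * 7.0 + 3.0)
        assert assign_genes(expr, centers)[0] == 2

    def test_exact_tie_breaks_to_lowest_index(self, rng):
        g = rng.standard_normal(10)
        z = (g - g.mean()) / g.std()
        centers = [z / np.linalg.norm(z), -z / np.linalg.norm(z)]
        expr = make_expr(g[None, :])
        assert assign_genes(expr, centers)[0] == 0

    def test_single_center_labels_everything_zero(self, rng):
        centers = [rng.standard_normal(8)]
        expr = make_expr(rng.standard_normal((6, 8)))
        assert set(assign_genes(expr, centers)) == {0}


class TestCenterUpdate:
    def test_recovers_planted_factors(self, rng):
        f0, f1 = rng.standard_normal((2, 30))
        block0 = f0 + 0.1 * rng.standard_normal((10, 30))
        block1 = f1 + 0.1 * rng.standard_normal((10, 30))
        expr = make_expr(np.vstack([block0, block1]))
        labels = np.array([0] * 10 + [1] * 10)
        centers, label_map = update_centers(expr, labels)
        assert label_map == {0: 0, 1: 1}
        assert abs(_cor(centers[0], f0)) >= 0.99
        assert abs(_cor(centers[1], f1)) >= 0.99

    def test_undersized_cluster_dropped_and_renumbered(self, rng):
        expr = make_expr(rng.standard_normal((7, 12)))
        labels = np.array([0, 0, 0, 1, 2, 2, 2])  # cluster 1 has 1 gene
        centers, label_map = update_centers(expr, labels, min_module_size=3)
        assert len(centers) == 2
        assert label_map == {0: 0, 2: 1}


class TestRunGcnaKpca:
    def test_planted_module_recovery_seed17(self):
        from sklearn.metrics import adjusted_rand_score

        expr, _, truth = gk.simulate_expression(gk.SimulationSpec(seed=17))
        part, trace = run_gcna_kpca(expr)
        genes = truth.module_gene_ids()
        ari = adjusted_rand_score(
            [truth.module_labels[g] for g in genes], [part.labels[g] for g in genes]
        )
        assert ari >= 0.9
        assert trace.converged

    def test_convergence_is_assignment_fixpoint(self):
        expr, _, _ = gk.simulate_expression(gk.SimulationSpec(seed=2))
        part, trace = run_gcna_kpca(expr)
        assert trace.converged
        centers = [part.eigengenes[k] for k in range(part.n_modules)]
        again = assign_genes(expr, centers)
        current = np.array([part.labels[g] for g in expr.gene_ids])
        np.testing.assert_array_equal(again, current)

    def test_final_labels_minimize_distance_exhaustively(self):
        expr, _, _ = gk.simulate_expression(gk.SimulationSpec(seed=3))
        part, _ = run_gcna_kpca(expr)
        centers = [part.eigengenes[k] for k in range(part.n_modules)]
        for g in expr.gene_ids:
            d = [correlation_distance(expr.gene_vector(g), c) for c in centers]
            assert d[part.labels[g]] == pytest.approx(min(d), abs=1e-12)

    def test_deterministic_given_seed(self):
        expr, _, _ = gk.simulate_expression(gk.SimulationSpec(seed=4))
        p1, _ = run_gcna_kpca(expr, config=KpcaConfig(seed=17))
        p2, _ = run_gcna_kpca(expr, config=KpcaConfig(seed=17))
        assert p1.labels == p2.labels
        for k in p1.eigengenes:
            np.testing.assert_array_equal(p1.eigengenes[k], p2.eigengenes[k])

    def test_max_iter_one_runs_single_iteration(self):
        expr, _, _ = gk.simulate_expression(gk.SimulationSpec(seed=5))
        _, trace = run_gcna_kpca(expr, config=KpcaConfig(max_iter=1))
        assert trace.n_iterations == 1
        assert trace.converged == (trace.label_changes[-1] == 0)

    def test_edgeless_network_advises_lower_threshold(self, rng):
        expr = make_expr(rng.standard_normal((10, 20)))
        with pytest.raises(gk.DataFormatError, match="threshold"):
            run_gcna_kpca(expr, threshold=0.999999)

    def test_isolated_genes_receive_labels(self):
        # background genes rarely reach |r| >= 0.65, yet every gene ends
        # up labeled after refinement.
        expr, _, _ = gk.simulate_expression(gk.SimulationSpec(seed=6))
        part, _ = run_gcna_kpca(expr)
        assert set(part.labels) == set(expr.gene_ids)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            KpcaConfig(max_iter=0)
        with pytest.raises(ValueError):
            KpcaConfig(min_module_size=1)
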