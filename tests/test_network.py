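"""MI estimation, threshold calibration, DPI pruning, regulon inference."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regact.network import (
    MIEdge,
    NetworkConfig,
    apply_dpi,
    calibrate_mi_threshold,
    estimate_mi,
    infer_regulons,
)
from regact.network import _rank_bins

from conftest import random_expression
from oracles import mi_from_pairs


class TestEstimateMi:
    def test_identical_vectors_ten_bins_give_ln10(self):
        x = np.arange(100, dtype=float)
        assert estimate_mi(x, x, 10) == pytest.approx(math.log(10), rel=1e-12)

    def test_constant_vector_gives_zero(self):
        x = np.arange(50, dtype=float)
        assert estimate_mi(x, np.full(50, 3.0)) == 0.0

    def test_matches_hand_computed_joint_histogram(self, rng):
        for _ in range(5):
            x = rng.standard_normal(64)
            y = x + rng.standard_normal(64)
            bx = _rank_bins(x, 8)
            by = _rank_bins(y, 8)
            assert estimate_mi(x, y, 8) == pytest.approx(
                mi_from_pairs(list(bx), list(by)), rel=1e-12
            )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetry_and_nonnegativity(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        mi = estimate_mi(x, y)
        assert mi >= 0.0
        assert mi == pytest.approx(estimate_mi(y, x), rel=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            estimate_mi(np.zeros(10), np.zeros(11))


class TestThresholdCalibration:
    def test_alpha_one_returns_null_minimum(self, rng):
        expr = random_expression(rng, n_genes=20, n_samples=30)
        cfg = NetworkConfig(alpha=1.0, n_permutations=50, seed=1)
        thr, null = calibrate_mi_threshold(expr, cfg, return_null=True)
        assert thr == null.min()

    def test_constant_matrix_gives_zero_threshold(self):
        import pandas as pd

        from regact.containers import ExpressionMatrix

        expr = ExpressionMatrix(
            pd.DataFrame(np.ones((5, 20)), index=list("abcde")), unit="log2fpkm"
        )
        assert calibrate_mi_threshold(expr, NetworkConfig(n_permutations=20)) == 0.0

    def test_threshold_is_rank_statistic_of_null(self, rng):
        expr = random_expression(rng, n_genes=15, n_samples=40)
        cfg = NetworkConfig(alpha=0.05, n_permutations=1000, seed=3)
        thr, null = calibrate_mi_threshold(expr, cfg, return_null=True)
        assert thr == sorted(null)[math.ceil(0.95 * 1000) - 1]
        # reproducible under the same seed
        thr2 = calibrate_mi_threshold(expr, cfg)
        assert thr2 == thr


class TestDpi:
    def test_weakest_triangle_edge_removed(self):
        edges = [MIEdge("x", "y", 0.8), MIEdge("y", "z", 0.7), MIEdge("x", "z", 0.3)]
        kept = {(e.regulator, e.target) for e in apply_dpi(edges, 0.0)}
        assert kept == {("x", "y"), ("y", "z")}

    def test_tolerance_scales_the_bound(self):
        edges = [MIEdge("x", "y", 0.8), MIEdge("y", "z", 0.7), MIEdge("x", "z", 0.3)]
        # bound is (1-0.2)*0.7 = 0.56: 0.3 removed, 0.60 would survive
        assert len(apply_dpi(edges, 0.2)) == 2
        edges[2] = MIEdge("x", "z", 0.60)
        assert len(apply_dpi(edges, 0.2)) == 3

    def test_no_triangles_unchanged(self):
        edges = [MIEdge("a", "b", 0.5), MIEdge("c", "d", 0.1)]
        assert apply_dpi(edges, 0.0) == edges

    def test_strongest_edge_of_triangle_always_survives(self, rng):
        for _ in range(20):
            w = rng.random(3) + 0.01
            edges = [
                MIEdge("x", "y", w[0]), MIEdge("y", "z", w[1]), MIEdge("x", "z", w[2])
            ]
            kept = apply_dpi(edges, 0.1)
            strongest = max(edges, key=lambda e: e.mi)
            assert strongest in kept

    def test_all_tests_against_pre_pruning_graph(self):
        # two triangles sharing the weak edge: evaluated on the original graph,
        # both conditions see the same weights
        edges = [
            MIEdge("a", "b", 1.0), MIEdge("b", "c", 0.9), MIEdge("a", "c", 0.2),
            MIEdge("c", "d", 1.0), MIEdge("a", "d", 0.95),
        ]
        kept = {(e.regulator, e.target) for e in apply_dpi(edges, 0.0)}
        assert ("a", "c") not in kept
        assert ("a", "d") in kept


class TestInferRegulons:
    def test_planted_edges_recovered(self, dev_cohort):
        net, expr, _ = dev_cohort
        cfg = NetworkConfig(alpha=0.05, n_permutations=300, min_regulon_size=1, seed=0)
        regulons = infer_regulons(expr, net.regulators, cfg)
        inferred = {(r, t) for r in regulons.regulators for t in regulons.targets(r)}
        truth = net.edge_set()
        tp = len(inferred & truth)
        assert tp / len(truth) >= 0.8
        assert tp / max(len(inferred), 1) >= 0.8

    def test_lower_alpha_never_adds_edges(self, dev_cohort):
        net, expr, _ = dev_cohort
        edge_sets = []
        for alpha in (0.2, 0.05, 0.01):
            cfg = NetworkConfig(
                alpha=alpha, n_permutations=300, min_regulon_size=1,
                edge_correction="none", seed=5,
            )
            regulons = infer_regulons(expr, net.regulators, cfg)
            edge_sets.append({(r, t) for r in regulons.regulators for t in regulons.targets(r)})
        assert edge_sets[2] <= edge_sets[1] <= edge_sets[0]

    def test_recovery_improves_with_sample_size(self):
        from regact import synthetic

        f1 = []
        for n in (50, 100, 200):
            net = synthetic.make_truth_network(3, 10, 80, seed=21)
            expr, _ = synthetic.simulate_expression_cohort(
                net, {"dev": n}, {"dev": {r: 0.0 for r in net.regulators}},
                noise_sd=0.5, seed=22, activity_sd=1.0,
            )
            cfg = NetworkConfig(n_permutations=300, min_regulon_size=1, seed=23)
            regulons = infer_regulons(expr, net.regulators, cfg)
            inferred = {(r, t) for r in regulons.regulators for t in regulons.targets(r)}
            truth = net.edge_set()
            tp = len(inferred & truth)
            prec = tp / max(len(inferred), 1)
            rec = tp / len(truth)
            f1.append(0.0 if tp == 0 else 2 * prec * rec / (prec + rec))
        assert f1[0] <= f1[1] + 0.05 and f1[1] <= f1[2] + 0.05 and f1[2] >= 0.9

    def test_oversized_min_regulon_gives_empty_set(self, dev_cohort):
        net, expr, _ = dev_cohort
        cfg = NetworkConfig(n_permutations=100, min_regulon_size=10_000, seed=0)
        assert len(infer_regulons(expr, net.regulators, cfg)) == 0

    def test_absent_regulators_raise(self, dev_cohort):
        _, expr, _ = dev_cohort
        with pytest.raises(ValueError):
            infer_regulons(expr, ["NOPE"], NetworkConfig(n_permutations=100))

    def test_provenance_records_configuration(self, dev_cohort):
        net, expr, _ = dev_cohort
        cfg = NetworkConfig(alpha=0.05, n_permutations=100, min_regulon_size=1, seed=9)
        prov = infer_regulons(expr, net.regulators, cfg).provenance
        for key in ("estimator", "n_bins", "threshold", "alpha", "dpi_tolerance", "seed"):
            assert key in prov
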