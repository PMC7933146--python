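"""Generators: planted structure, noiseless closed forms, determinism."""

import json

import numpy as np
import pandas as pd
import pytest

from regact import synthetic
from regact.errors import PlacementError, SizingError

from oracles import brute_force_overlap_count


class TestTruthNetwork:
    def test_zero_overlap_gives_disjoint_regulons(self):
        net = synthetic.make_truth_network(2, 3, 100, overlap_fraction=0.0, seed=1)
        t1 = {t for t, _, _ in net.targets_of["TF01"]}
        t2 = {t for t, _, _ in net.targets_of["TF02"]}
        assert len(t1) == len(t2) == 3
        assert not t1 & t2

    def test_overlap_fraction_shares_exact_target_count(self):
        net = synthetic.make_truth_network(2, 4, 100, overlap_fraction=0.5, seed=1)
        t1 = {t for t, _, _ in net.targets_of["TF01"]}
        t2 = {t for t, _, _ in net.targets_of["TF02"]}
        assert len(t1 & t2) == 2

    def test_identical_seed_identical_serialization(self, tmp_path):
        blobs = []
        for run in range(2):
            net = synthetic.make_truth_network(3, 5, 60, overlap_fraction=0.2, seed=7)
            blobs.append(json.dumps(net.to_dict(), sort_keys=True))
        assert blobs[0] == blobs[1]

    def test_round_trip_from_recorded_params(self):
        net = synthetic.make_truth_network(3, 5, 60, overlap_fraction=0.2, seed=9)
        rebuilt = synthetic.make_truth_network(**net.params)
        assert rebuilt.to_dict() == net.to_dict()

    def test_impossible_budget_raises(self):
        with pytest.raises(SizingError):
            synthetic.make_truth_network(10, 30, 100, seed=0)

    def test_no_self_targets_and_positive_effects(self):
        net = synthetic.make_truth_network(5, 8, 80, overlap_fraction=0.3, seed=2)
        for r, targets in net.targets_of.items():
            for t, eff, sign in targets:
                assert t != r and eff > 0 and sign in (-1, 1)


class TestExpressionCohort:
    def test_noiseless_targets_equal_effect_times_activity(self, small_network):
        expr, _ = synthetic.simulate_expression_cohort(
            small_network, {"g": 3},
            {"g": {"TF01": 2.0, "TF02": 0.0}},
            noise_sd=0.0, seed=0,
        )
        for t, eff, sign in small_network.targets_of["TF01"]:
            assert np.allclose(expr.values.loc[t], sign * eff * 2.0)
        # non-target, non-TF01-regulated genes are silent
        touched = {t for t, _, _ in small_network.targets_of["TF01"]}
        silent = [g for g in expr.gene_ids if g not in touched | {"TF01"}]
        assert np.allclose(expr.values.loc[silent], 0.0)

    def test_two_group_mean_difference_matches_twice_effect(self, small_network):
        expr, truth = synthetic.simulate_expression_cohort(
            small_network, {"wt": 40, "mut": 40},
            {
                "wt": {"TF01": 1.0, "TF02": 0.0},
                "mut": {"TF01": -1.0, "TF02": 0.0},
            },
            noise_sd=0.3, seed=5,
        )
        groups = pd.Series(truth.group_of)
        wt = groups.index[groups == "wt"]
        mut = groups.index[groups == "mut"]
        for t, eff, sign in small_network.targets_of["TF01"]:
            diff = expr.values.loc[t, wt].mean() - expr.values.loc[t, mut].mean()
            assert diff == pytest.approx(2.0 * eff * sign, abs=0.35)

    def test_seed_determinism(self, small_network):
        kw = dict(
            groups={"g": 4},
            activity_profiles={"g": {"TF01": 1.0, "TF02": -1.0}},
            noise_sd=0.5, seed=11,
        )
        a, _ = synthetic.simulate_expression_cohort(small_network, **kw)
        b, _ = synthetic.simulate_expression_cohort(small_network, **kw)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_profile_missing_regulator_raises(self, small_network):
        with pytest.raises(KeyError):
            synthetic.simulate_expression_cohort(
                small_network, {"g": 3}, {"g": {"TF01": 1.0}}, noise_sd=0.1, seed=0
            )


class TestKnockdown:
    def test_noiseless_log2fc_values(self):
        net = synthetic.make_truth_network(
            2, 4, 30, seed=3, effect_range=(1.0, 1.0), repressed_fraction=0.5
        )
        fc = synthetic.simulate_knockdown_profiles(net, "TF01", -1.0, 0.0, seed=0)
        for t, eff, sign in net.targets_of["TF01"]:
            assert fc[t] == pytest.approx(-1.0 if sign > 0 else 1.0)
        untouched = set(net.gene_ids) - {t for t, _, _ in net.targets_of["TF01"]} - {"TF01"}
        assert (fc[sorted(untouched)] == 0.0).all()

    def test_unknown_regulator_raises(self, small_network):
        with pytest.raises(KeyError):
            synthetic.simulate_knockdown_profiles(small_network, "NOPE", -1.0, 0.0, 0)


class TestPeakSets:
    @pytest.mark.parametrize("fraction", [0.0, 0.8, 1.0])
    def test_planted_fraction_exact_by_brute_force(self, fraction):
        ref, qry = synthetic.simulate_peak_sets(
            500_000, 60, 50, fraction, peak_width=150, seed=3
        )
        hits = brute_force_overlap_count(qry.intervals(), ref.intervals())
        assert hits == round(fraction * 50)

    def test_intervals_sorted_valid(self):
        ref, qry = synthetic.simulate_peak_sets(200_000, 30, 20, 0.5, seed=1)
        for ps in (ref, qry):
            assert (ps.df["start"] < ps.df["end"]).all()
            assert (ps.df["start"] >= 0).all()
            assert ps.df["start"].is_monotonic_increasing

    def test_crowded_genome_raises(self):
        with pytest.raises((SizingError, PlacementError)):
            synthetic.simulate_peak_sets(10_000, 100, 100, 0.5, peak_width=200, seed=0)


class TestSpectralCounts:
    def test_zero_control_mean_gives_zero_control_counts(self):
        t = synthetic.simulate_spectral_counts(50, 10, 20.0, 0.0, n_replicates=2, seed=1)
        enriched = sorted(t.truth_enriched)
        assert (t.counts.loc[enriched, t.control_runs].to_numpy() == 0).all()
        background = [p for p in t.proteins if p not in t.truth_enriched]
        assert (t.counts.loc[background].to_numpy() == 0).all()

    def test_determinism(self):
        a = synthetic.simulate_spectral_counts(40, 5, 10.0, 1.0, seed=9)
        b = synthetic.simulate_spectral_counts(40, 5, 10.0, 1.0, seed=9)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        assert a.truth_enriched == b.truth_enriched

    def test_negative_mean_raises(self):
        with pytest.raises(ValueError):
            synthetic.simulate_spectral_counts(10, 2, -1.0, 1.0, seed=0)


class TestAlleleCounts:
    @pytest.mark.parametrize("fraction,col", [(0.0, "alt_count"), (1.0, "ref_count")])
    def test_degenerate_fractions(self, fraction, col):
        t = synthetic.simulate_allele_counts(100, fraction, n_sites=20, seed=0)
        assert (t[col] == 0).all()

    def test_mean_fraction_within_three_se(self):
        # binomial s.e. at p=0.5, depth 1000, 100 sites: 0.0158 / sqrt(100)
        t = synthetic.simulate_allele_counts(1000, 0.5, n_sites=100, seed=2)
        se = np.sqrt(0.5 * 0.5 / 1000)
        assert abs((t["alt_count"] / 1000).mean() - 0.5) < 3 * se

    def test_invalid_fraction_raises(self):
        with pytest.raises(ValueError):
            synthetic.simulate_allele_counts(100, 1.5, seed=0)
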