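"""Signature construction, signal-to-noise ranking, and weighted-KS GSEA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regact.containers import ExpressionMatrix, GeneSet
from regact.gsea import (
    SetCoverageError,
    build_eprotein_signature,
    enrichment_score,
    gsea,
    rank_by_signal2noise,
    signal2noise,
)
from regact.gsea import _null_es

from oracles import gsea_running_sum


class TestSignature:
    @pytest.mark.parametrize(
        "e2a,heb,tal1,included",
        [
            (-0.7, -0.6, 0.4, True),
            (-0.7, -0.4, 0.4, False),  # HEB fails the -0.5 threshold
            (-0.7, -0.6, -0.2, False),  # TAL1 direction fails
            (-0.5, -0.6, 0.4, False),  # boundary is strict
        ],
    )
    def test_rule_application(self, e2a, heb, tal1, included):
        genes = ["g_test", "g_pass"]
        fc = lambda a, b: pd.Series([a, b], index=genes)
        sig = build_eprotein_signature(fc(e2a, -1.0), fc(heb, -1.0), fc(tal1, 1.0))
        assert ("g_test" in sig.members) == included

    def test_intersection_of_gene_universes(self):
        a = pd.Series({"g1": -1.0, "g2": -1.0})
        b = pd.Series({"g2": -1.0, "g3": -1.0})
        c = pd.Series({"g2": 1.0, "g4": 1.0})
        assert build_eprotein_signature(a, b, c).members == frozenset({"g2"})

    def test_disjoint_universes_raise(self):
        with pytest.raises(ValueError):
            build_eprotein_signature(
                pd.Series({"a": -1.0}), pd.Series({"b": -1.0}), pd.Series({"c": 1.0})
            )


class TestSignal2Noise:
    def test_plain_formula(self):
        assert signal2noise(2, 1, 0.5, 0.3) == pytest.approx(1.25)

    def test_sd_floor_on_constant_groups(self):
        # sds 0 -> floors max(0.2*|mu|, 0.2): 0.4 and 0.2 -> 1/0.6
        assert signal2noise(2, 1, 0.0, 0.0) == pytest.approx(1.6667, abs=1e-4)

    def test_identical_groups_give_zero(self):
        assert signal2noise(1.5, 1.5, 0.4, 0.4) == 0.0

    def test_ranking_filters_low_fpkm_and_breaks_ties_by_id(self):
        values = pd.DataFrame(
            {
                "s1": [10.0, 10.0, 0.1, 5.0],
                "s2": [12.0, 12.0, 0.2, 6.0],
                "s3": [1.0, 1.0, 0.1, 5.0],
                "s4": [2.0, 2.0, 0.2, 6.0],
            },
            index=["gB", "gA", "low", "flat"],
        )
        expr = ExpressionMatrix(values, unit="fpkm")
        groups = pd.Series(["hi", "hi", "lo", "lo"], index=values.columns)
        ranked = rank_by_signal2noise(expr, groups, "hi", "lo", min_fpkm=1.0)
        assert "low" not in ranked.index
        # gA and gB are identical -> tie broken lexicographically
        assert list(ranked.index[:2]) == ["gA", "gB"]
        assert ranked.is_monotonic_decreasing


class TestEnrichmentScore:
    def test_top_gene_set_reaches_one(self):
        ranked = pd.Series([2.0, 1.0, 1.0, 1.0], index=["a", "b", "c", "d"])
        res = enrichment_score(ranked, GeneSet("s", frozenset({"a"})))
        assert res.es == pytest.approx(1.0)
        assert res.leading_edge == ["a"]

    def test_bottom_gene_set_reaches_minus_one(self):
        ranked = pd.Series([4.0, 3.0, 2.0, 1.0], index=["a", "b", "c", "d"])
        res = enrichment_score(ranked, GeneSet("s", frozenset({"d"})))
        assert res.es == pytest.approx(-1.0)
        assert res.leading_edge == ["d"]

    def test_explicit_running_sum(self):
        ranked = pd.Series([2.0, 1.0, 1.0, 1.0], index=["a", "b", "c", "d"])
        res = enrichment_score(ranked, GeneSet("s", frozenset({"a"})))
        assert np.allclose(res.running_sum, [1.0, 2 / 3, 1 / 3, 0.0])

    def test_matches_brute_force_oracle_on_random_fixtures(self, rng):
        genes = [f"g{i:02d}" for i in range(40)]
        for trial in range(20):
            metrics = np.sort(rng.standard_normal(40))[::-1]
            ranked = pd.Series(metrics, index=genes)
            members = frozenset(rng.choice(genes, size=rng.integers(1, 15), replace=False))
            res = enrichment_score(ranked, GeneSet("s", members))
            es_oracle, trace_oracle = gsea_running_sum(
                metrics, [g in members for g in genes]
            )
            assert np.allclose(res.running_sum, trace_oracle)
            assert res.es == pytest.approx(es_oracle, rel=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_es_bounded_by_one(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(30)]
        ranked = pd.Series(np.sort(rng.standard_normal(30))[::-1], index=genes)
        members = frozenset(rng.choice(genes, size=int(rng.integers(1, 30)), replace=False))
        assert abs(enrichment_score(ranked, GeneSet("s", members)).es) <= 1.0 + 1e-12

    def test_no_covered_members_raises(self):
        ranked = pd.Series([1.0], index=["a"])
        with pytest.raises(SetCoverageError):
            enrichment_score(ranked, GeneSet("s", frozenset({"zz"})))

    def test_fast_null_path_matches_main_path(self, rng):
        genes = [f"g{i:02d}" for i in range(50)]
        metrics = np.sort(rng.standard_normal(50))[::-1]
        ranked = pd.Series(metrics, index=genes)
        null = _null_es(metrics, 8, 200, np.random.default_rng(4), 1.0)
        rng2 = np.random.default_rng(4)
        expected = []
        for _ in range(200):
            pos = np.sort(np.argsort(rng2.random(50))[:8])
            members = frozenset(np.asarray(genes)[pos])
            expected.append(enrichment_score(ranked, GeneSet("s", members)).es)
        assert np.allclose(null, expected)


class TestGsea:
    def _null_ranked(self, rng, n=60):
        genes = [f"g{i:03d}" for i in range(n)]
        metric = pd.Series(rng.standard_normal(n), index=genes)
        return metric.loc[sorted(genes, key=lambda g: (-metric[g], g))]

    def test_small_sets_skipped_per_set_min(self, rng):
        ranked = self._null_ranked(rng)
        small = GeneSet("small", frozenset(ranked.index[:3]))
        big = GeneSet("big", frozenset(ranked.index[:6]))
        res = gsea(ranked, [small, big], n_permutations=100, set_min=4, seed=0)
        assert list(res["set"]) == ["big"]
        assert res.attrs["skipped"][0][0] == "small"

    def test_p_lower_bound_and_nes_sign(self, rng):
        ranked = self._null_ranked(rng)
        top = GeneSet("top", frozenset(ranked.index[:6]))
        res = gsea(ranked, [top], n_permutations=200, seed=1).iloc[0]
        assert res["p"] >= 1 / 201
        assert np.sign(res["nes"]) == np.sign(res["es"])

    def test_unsupported_permutation_mode_rejected(self, rng):
        ranked = self._null_ranked(rng)
        with pytest.raises(ValueError):
            gsea(ranked, [GeneSet("s", frozenset(ranked.index[:5]))], permute="phenotype")

    def test_too_few_permutations_rejected(self, rng):
        ranked = self._null_ranked(rng)
        with pytest.raises(ValueError):
            gsea(ranked, [GeneSet("s", frozenset(ranked.index[:5]))], n_permutations=0)

    def test_sign_flip_on_negated_reversed_list(self, rng):
        ranked = self._null_ranked(rng)
        members = frozenset(rng.choice(ranked.index, size=8, replace=False))
        flipped = (-ranked).iloc[::-1]
        es_fwd = enrichment_score(ranked, GeneSet("s", members)).es
        es_rev = enrichment_score(flipped, GeneSet("s", members)).es
        assert es_fwd == pytest.approx(-es_rev, rel=1e-9)
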