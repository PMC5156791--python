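"""Hypergeometric enrichment, FDR flags and pathway-coverage fractions."""

import itertools
import math

import numpy as np
import pytest

from conftest import make_condition
from mirpoma.data_io import GeneSet, GeneSetCollection, ValidationError
from mirpoma.enrichment import (
    PathwayCoverage,
    enrich,
    hypergeom_tail,
    pathway_coverage,
)
from mirpoma.regnet import compute_stats
from mirpoma.selection import select_candidates


def collection(**sets):
    return GeneSetCollection(
        sets={k: GeneSet(k, "", frozenset(v)) for k, v in sets.items()}
    )


def brute_force_tail(overlap, query_size, set_size, universe_size):
    """Enumerate every possible query draw from the universe."""
    universe = list(range(universe_size))
    pathway = set(range(set_size))
    hits = total = 0
    for draw in itertools.combinations(universe, query_size):
        total += 1
        if len(pathway & set(draw)) >= overlap:
            hits += 1
    return hits / total


class TestHypergeomTail:
    def test_exact_small_example(self):
        # universe 10, pathway 5, query 4, overlap 4 -> C(5,4)/C(10,4)
        assert hypergeom_tail(4, 4, 5, 10) == pytest.approx(5 / 210)

    def test_zero_overlap_is_one(self):
        assert hypergeom_tail(0, 10, 20, 100) == 1.0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            universe_size = int(rng.integers(4, 13))
            set_size = int(rng.integers(1, universe_size + 1))
            query_size = int(rng.integers(1, universe_size + 1))
            overlap = int(rng.integers(0, min(set_size, query_size) + 1))
            assert hypergeom_tail(overlap, query_size, set_size, universe_size) == pytest.approx(
                brute_force_tail(overlap, query_size, set_size, universe_size)
            )

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(1)
        universe_size, set_size, query_size = 200, 40, 25
        n_draws = 10**6
        counts = rng.hypergeometric(set_size, universe_size - set_size, query_size, n_draws)
        overlap = 9
        p_mc = float(np.mean(counts >= overlap))
        p_an = hypergeom_tail(overlap, query_size, set_size, universe_size)
        se = math.sqrt(p_an * (1 - p_an) / n_draws)
        assert abs(p_mc - p_an) < 3 * se

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_tail(5, 4, 10, 100)
        with pytest.raises(ValidationError):
            hypergeom_tail(1, 5, 200, 100)

    def test_log_space_stable_in_extreme_tail(self):
        p = hypergeom_tail(50, 50, 50, 10_000)
        assert 0 < p < 1e-100


class TestEnrich:
    def test_planted_pathway_ranks_first(self):
        rng = np.random.default_rng(2)
        universe = frozenset(f"g{i}" for i in range(2000))
        genes = sorted(universe)
        target = frozenset(genes[:30])
        sets = {"target_pw": target}
        for i in range(20):
            sets[f"bg{i:02d}"] = frozenset(rng.choice(genes, size=30, replace=False))
        results = enrich(target, collection(**sets), universe)
        assert results[0].pathway_name == "target_pw"
        assert results[0].enriched and results[0].overlap == 30

    def test_disjoint_query_nothing_enriched(self):
        universe = frozenset(f"g{i}" for i in range(100))
        sets = collection(pw=frozenset({"g1", "g2", "g3"}))
        results = enrich(frozenset({"g50", "g51"}), sets, universe)
        assert all(not r.enriched for r in results)
        assert results[0].p_raw == 1.0

    def test_pathway_order_invariance(self):
        universe = frozenset(f"g{i}" for i in range(50))
        a = collection(pw1={"g1", "g2"}, pw2={"g2", "g3", "g4"})
        b = collection(pw2={"g2", "g3", "g4"}, pw1={"g1", "g2"})
        query = frozenset({"g1", "g2", "g3"})
        ra = {r.pathway_name: (r.p_raw, r.fdr) for r in enrich(query, a, universe)}
        rb = {r.pathway_name: (r.p_raw, r.fdr) for r in enrich(query, b, universe)}
        assert ra == rb

    def test_query_outside_universe_dropped_then_error_if_empty(self):
        universe = frozenset({"g1", "g2"})
        sets = collection(pw={"g1"})
        results = enrich(frozenset({"g1", "gX"}), sets, universe)
        assert results[0].query_size == 1
        with pytest.raises(ValidationError, match="empty query"):
            enrich(frozenset({"gX"}), sets, universe)

    def test_enriched_flag_requires_both_thresholds(self):
        for r in enrich(
            frozenset({"g1", "g2"}),
            collection(pw={"g1", "g2"}, other={"g5", "g6"}),
            frozenset(f"g{i}" for i in range(7)),
        ):
            assert r.enriched == (r.p_raw < 0.05 and r.fdr < 0.05)

    def test_matches_exhaustive_oracle_on_tiny_universe(self):
        # every (overlap, sizes) configuration on a <=12-gene universe
        universe = frozenset(f"g{i}" for i in range(10))
        sets = collection(pw={"g0", "g1", "g2", "g3", "g4"})
        query = frozenset({"g0", "g1", "g2", "g9"})
        (r,) = enrich(query, sets, universe)
        assert r.p_raw == pytest.approx(brute_force_tail(3, 4, 5, 10))


class TestPathwayCoverage:
    def _setup(self):
        cond = make_condition(
            {"m1": {"g1", "g2", "g3"}, "m2": {"g3", "g4"}, "m3": {"g9"}}
        )
        stats = compute_stats(cond)
        # fabricate a candidate set containing m1 and m2
        from mirpoma.selection import CandidateRecord, CandidateSet

        by_id = {s.mirna_id: s for s in stats}
        cands = CandidateSet(
            condition_label="t",
            candidates=[
                CandidateRecord("m1", 0.01, 0.01, by_id["m1"]),
                CandidateRecord("m2", 0.01, 0.01, by_id["m2"]),
            ],
            alpha=0.05,
            all_stats=stats,
        )
        return cond, cands

    def test_counts_enriched_pathways_touching_unique_targets(self):
        from mirpoma.enrichment import EnrichmentResult

        cond, cands = self._setup()
        sets = collection(pwA={"g1", "g9"}, pwB={"g4"}, pwC={"g3"})
        enriched = [
            EnrichmentResult("pwA", 2, 3, 1, 0.01, 0.01, True),
            EnrichmentResult("pwB", 1, 3, 1, 0.01, 0.01, True),
            EnrichmentResult("pwC", 1, 3, 1, 0.5, 0.5, False),
        ]
        cov = {c.mirna_id: c for c in pathway_coverage(cond, cands, enriched, sets)}
        # m1 unique targets {g1, g2}: touches pwA only (pwC not enriched)
        assert (cov["m1"].n_regulated, cov["m1"].n_enriched_total) == (1, 2)
        # m2 unique targets {g4}: touches pwB
        assert cov["m2"].n_regulated == 1

    def test_no_enriched_pathways_empty_with_warning(self, caplog):
        import logging

        cond, cands = self._setup()
        sets = collection(pwA={"g1"})
        with caplog.at_level(logging.WARNING):
            out = pathway_coverage(cond, cands, [], sets)
        assert out == []
        assert any("no enriched" in r.message for r in caplog.records)

    def test_candidate_with_empty_unique_targets_scores_zero(self):
        from mirpoma.enrichment import EnrichmentResult
        from mirpoma.selection import CandidateRecord, CandidateSet

        cond = make_condition({"m1": {"g1"}, "m2": {"g1"}})
        stats = compute_stats(cond)
        by_id = {s.mirna_id: s for s in stats}
        cands = CandidateSet(
            "t", [CandidateRecord("m1", 0.01, 0.01, by_id["m1"])], 0.05, stats
        )
        sets = collection(pw={"g1"})
        enriched = [EnrichmentResult("pw", 1, 1, 1, 0.001, 0.001, True)]
        (cov,) = pathway_coverage(cond, cands, enriched, sets)
        assert cov.n_regulated == 0 and cov.fraction == 0.0

    @pytest.mark.parametrize(
        "n_reg, n_total, percent",
        [(29, 35, 83.0), (13, 18, 72.0), (16, 35, 46.0), (24, 35, 69.0)],
    )
    def test_published_coverage_percentages(self, n_reg, n_total, percent):
        assert PathwayCoverage("m", n_reg, n_total).percent == percent

    def test_coverage_never_exceeds_total(self):
        cond, cands = self._setup()
        from mirpoma.enrichment import EnrichmentResult

        sets = collection(pwA={"g1", "g2", "g3", "g4"}, pwB={"g2", "g4"})
        enriched = [
            EnrichmentResult("pwA", 4, 3, 2, 0.01, 0.01, True),
            EnrichmentResult("pwB", 2, 3, 1, 0.02, 0.02, True),
        ]
        for c in pathway_coverage(cond, cands, enriched, sets):
            assert 0 <= c.n_regulated <= c.n_enriched_total
            assert 0.0 <= c.fraction <= 1.0
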