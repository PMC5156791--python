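"""Hypergeometric pathway enrichment and per-miRNA pathway coverage.

The query is the union of the candidates' uniquely regulated (NOD) genes.
For each pathway, the upper-tail hypergeometric probability
P(X >= overlap), X ~ Hypergeom(universe, pathway-in-universe, query), gives
the raw p-value; Benjamini-Hochberg over tested pathways gives the FDR; a
pathway is called enriched when both p < alpha and FDR < alpha.

Pathway coverage then asks, per candidate miRNA, what fraction of the
enriched pathways its unique-target set touches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .data_io import GeneSetCollection, ValidationError
from .diff_expr import adjust_bh
from .regnet import ConditionNetwork, round_half_up, unique_targets
from .selection import CandidateSet

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


def hypergeom_tail(overlap: int, query_size: int, set_size: int, universe_size: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe_size, set_size, query_size).

    Computed by summing log-pmf terms for stability at extreme tails.
    """
    if not (0 <= overlap <= min(query_size, set_size)):
        raise ValidationError(
            f"inconsistent counts: overlap={overlap}, query={query_size}, set={set_size}"
        )
    if max(query_size, set_size) > universe_size:
        raise ValidationError("set or query larger than the universe")
    if overlap == 0:
        return 1.0
    ks = np.arange(overlap, min(query_size, set_size) + 1)
    logp = hypergeom.logpmf(ks, universe_size, set_size, query_size)
    return float(min(1.0, np.exp(logsumexp(logp))))


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_name: str
    set_size: int       # pathway genes within the universe
    query_size: int
    overlap: int
    p_raw: float
    fdr: float
    enriched: bool


def enrich(
    query: frozenset[str] | set[str],
    sets: GeneSetCollection,
    universe: frozenset[str] | set[str],
    alpha: float = DEFAULT_ALPHA,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Query genes outside the universe are dropped (logged); pathways with no
    gene in the universe are not tested.  Results are sorted by ascending
    raw p (ties by name).
    """
    universe = frozenset(universe)
    if not universe:
        raise ValidationError("empty universe")
    query = frozenset(query)
    outside = query - universe
    if outside:
        log.warning("%d query gene(s) outside the universe dropped", len(outside))
    query &= universe
    if not query:
        raise ValidationError("empty query after restricting to the universe")

    names, overlaps, set_sizes, pvals = [], [], [], []
    for gs in sets:
        in_universe = gs.genes & universe
        if not in_universe:
            continue
        k = len(in_universe & query)
        names.append(gs.name)
        set_sizes.append(len(in_universe))
        overlaps.append(k)
        pvals.append(hypergeom_tail(k, len(query), len(in_universe), len(universe)))
    if not names:
        return []
    fdrs = adjust_bh(np.array(pvals))
    results = [
        EnrichmentResult(
            pathway_name=nm,
            set_size=sz,
            query_size=len(query),
            overlap=k,
            p_raw=p,
            fdr=float(f),
            enriched=bool(p < alpha and f < alpha),
        )
        for nm, sz, k, p, f in zip(names, set_sizes, overlaps, pvals, fdrs)
    ]
    results.sort(key=lambda r: (r.p_raw, r.pathway_name))
    return results


@dataclass(frozen=True)
class PathwayCoverage:
    """How many of the enriched pathways a miRNA's gene set touches."""

    mirna_id: str
    n_regulated: int
    n_enriched_total: int

    @property
    def fraction(self) -> float:
        return self.n_regulated / self.n_enriched_total

    @property
    def percent(self) -> float:
        """Whole-number percentage, half-up (29/35 -> 83)."""
        return round_half_up(100.0 * self.fraction, 0)


def pathway_coverage(
    cond: ConditionNetwork,
    candidates: CandidateSet,
    enriched: list[EnrichmentResult],
    sets: GeneSetCollection,
    target_mode: str = "unique",
) -> list[PathwayCoverage]:
    """Per-candidate coverage of the significantly enriched pathways.

    A pathway counts as regulated by miRNA m when its gene set intersects
    m's unique-target (NOD) set; ``target_mode="all"`` uses all of m's
    targets instead.  With no enriched pathways an empty list is returned
    with a warning.
    """
    if target_mode not in {"unique", "all"}:
        raise ValidationError(f"target_mode must be 'unique' or 'all', got {target_mode!r}")
    sig = [r for r in enriched if r.enriched]
    if not sig:
        log.warning("%s: no enriched pathways; coverage is empty", cond.condition_label)
        return []
    total = len(sig)
    out = []
    for c in candidates.candidates:
        genes = (
            unique_targets(cond, c.mirna_id)
            if target_mode == "unique"
            else cond.targets(c.mirna_id)
        )
        n_reg = sum(1 for r in sig if sets[r.pathway_name].genes & genes)
        out.append(PathwayCoverage(c.mirna_id, n_reg, total))
    return out


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway": [r.pathway_name for r in results],
            "set_size": [r.set_size for r in results],
            "query_size": [r.query_size for r in results],
            "overlap": [r.overlap for r in results],
            "p_raw": [r.p_raw for r in results],
            "fdr": [r.fdr for r in results],
            "enriched": [r.enriched for r in results],
        }
    )


def coverage_table(coverage: list[PathwayCoverage]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mirna": [c.mirna_id for c in coverage],
            "pathways": [c.n_regulated for c in coverage],
            "pathway_fraction": [round_half_up(c.fraction, 2) for c in coverage],
            "pathway_percent": [c.percent for c in coverage],
        }
    )
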