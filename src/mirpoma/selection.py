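"""Candidate-biomarker selection from NOD/TFP outlier statistics.

A miRNA is called a candidate biomarker when both its NOD and its TFP sit
significantly above the rest of the condition network.  For each miRNA m
the one-sample Wilcoxon signed-rank test asks whether the other miRNAs'
statistic values are located below m's value (one-sided, p < alpha on both
statistics, raw p-values with no multiple-testing correction).

The signed-rank p-value is exact (full enumeration of sign assignments via
a subset-sum convolution, valid under ties through average ranks) for up to
25 nonzero differences, and a normal approximation with tie correction and
continuity correction beyond that.

A permutation-based alternative is provided: gene endpoints of the
condition network are shuffled (preserving each miRNA's out-degree and the
overall gene in-degree pool), and per-miRNA empirical p-values are taken
from the null NOD/TFP distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .data_io import RegulatoryNetwork, ValidationError
from .regnet import ConditionNetwork, MiRNAStats, compute_stats

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


class DegenerateTestError(ValidationError):
    """All differences are zero: the signed-rank test carries no information."""


def _exact_sf_dist(ranks: np.ndarray) -> np.ndarray:
    """Counts of sign assignments per value of 2*W+ (subset-sum convolution)."""
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        counts[r:] = counts[r:] + counts[: counts.size - r]
    return counts


def signed_rank_pvalue(
    values, location: float, alternative: str, method: str = "auto"
) -> float:
    """One-sample Wilcoxon signed-rank p-value of H0: median(values) = location.

    Zero differences are dropped; tied absolute differences receive average
    ranks.  ``alternative="greater"`` asks whether the values sit above the
    location, ``"less"`` whether they sit below.  ``method`` selects the
    null distribution: ``"exact"`` (full enumeration, valid under ties),
    ``"approx"`` (normal with tie and continuity corrections) or ``"auto"``
    (exact up to 25 nonzero differences).
    """
    if alternative not in {"greater", "less"}:
        raise ValidationError(f"alternative must be 'greater' or 'less', got {alternative!r}")
    if method not in {"auto", "exact", "approx"}:
        raise ValidationError(f"unknown method {method!r}")
    diffs = np.asarray(values, dtype=float) - float(location)
    diffs = diffs[diffs != 0]
    n = diffs.size
    if n == 0:
        raise DegenerateTestError("degenerate test: all differences are zero")
    ranks = sps.rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())

    if method == "exact" or (method == "auto" and n <= 25):
        counts = _exact_sf_dist(ranks)
        w2 = int(np.rint(2 * w_plus))
        denom = 2.0**n
        if alternative == "greater":
            return float(counts[w2:].sum() / denom)
        return float(counts[: w2 + 1].sum() / denom)

    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= float(((tie_counts**3 - tie_counts) / 48.0).sum())
    sd = np.sqrt(var)
    if alternative == "greater":
        z = (w_plus - mean - 0.5) / sd
        return float(sps.norm.sf(z))
    z = (w_plus - mean + 0.5) / sd
    return float(sps.norm.cdf(z))


@dataclass(frozen=True)
class CandidateRecord:
    mirna_id: str
    p_nod: float
    p_tfp: float
    stats: MiRNAStats


@dataclass
class CandidateSet:
    """Selected biomarker miRNAs with their selection p-values."""

    condition_label: str
    candidates: list[CandidateRecord]
    alpha: float
    all_stats: list[MiRNAStats]
    pvalues: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def ids(self) -> frozenset[str]:
        return frozenset(c.mirna_id for c in self.candidates)


def select_candidates(
    stats: list[MiRNAStats],
    alpha: float = DEFAULT_ALPHA,
    condition_label: str = "",
) -> CandidateSet:
    """Select miRNAs whose NOD and TFP are both significantly large.

    For each miRNA m, the NOD values of all other miRNAs are tested against
    location NOD(m) with alternative "less" (and likewise for TFP); m is a
    candidate iff both p-values are below alpha.  A degenerate test (all
    other values equal to m's) makes m a non-candidate, logged.  Candidates
    are ordered by descending NOD, ties by descending TFP then ID.
    """
    if len(stats) < 3:
        raise ValidationError(f"need >=3 miRNAs for selection, got {len(stats)}")
    nod = np.array([s.nod for s in stats], dtype=float)
    tfp = np.array([s.tfp for s in stats], dtype=float)
    pvalues: dict[str, tuple[float, float]] = {}
    selected: list[CandidateRecord] = []
    for i, s in enumerate(stats):
        others_nod = np.delete(nod, i)
        others_tfp = np.delete(tfp, i)
        try:
            p_nod = signed_rank_pvalue(others_nod, nod[i], "less")
            p_tfp = signed_rank_pvalue(others_tfp, tfp[i], "less")
        except DegenerateTestError:
            log.info("%s: degenerate signed-rank test, not a candidate", s.mirna_id)
            pvalues[s.mirna_id] = (np.nan, np.nan)
            continue
        pvalues[s.mirna_id] = (p_nod, p_tfp)
        if p_nod < alpha and p_tfp < alpha:
            selected.append(CandidateRecord(s.mirna_id, p_nod, p_tfp, s))
    selected.sort(key=lambda c: (-c.stats.nod, -c.stats.tfp, c.mirna_id))
    return CandidateSet(
        condition_label=condition_label,
        candidates=selected,
        alpha=alpha,
        all_stats=list(stats),
        pvalues=pvalues,
    )


def _rewire(network: RegulatoryNetwork, rng: np.random.Generator) -> ConditionNetwork:
    """Shuffle gene endpoints across edge slots (out-degrees preserved)."""
    edges = sorted(network.edges)
    genes = np.array([g for _, g in edges])
    rng.shuffle(genes)
    rewired = frozenset((m, g) for (m, _), g in zip(edges, genes))
    sub = RegulatoryNetwork(edges=rewired, tf_genes=network.tf_genes & frozenset(genes))
    return ConditionNetwork(network=sub, condition_label="null")


def select_candidates_permutation(
    cond: ConditionNetwork,
    alpha: float = DEFAULT_ALPHA,
    n_iters: int = 1000,
    seed: int = 0,
) -> CandidateSet:
    """Permutation-null alternative to the signed-rank selection.

    Empirical p-values: p = (1 + #{null >= observed}) / (n_iters + 1) per
    miRNA for NOD and TFP against rewired-network null distributions.
    """
    stats = compute_stats(cond)
    if len(stats) < 3:
        raise ValidationError(f"need >=3 miRNAs for selection, got {len(stats)}")
    rng = np.random.default_rng(seed)
    obs = {s.mirna_id: s for s in stats}
    ge_nod = {m: 0 for m in obs}
    ge_tfp = {m: 0 for m in obs}
    for _ in range(n_iters):
        null_stats = {s.mirna_id: s for s in compute_stats(_rewire(cond.network, rng))}
        for m, s in obs.items():
            ns = null_stats[m]
            if ns.nod >= s.nod:
                ge_nod[m] += 1
            if ns.tfp >= s.tfp:
                ge_tfp[m] += 1
    pvalues = {
        m: ((1 + ge_nod[m]) / (n_iters + 1), (1 + ge_tfp[m]) / (n_iters + 1)) for m in obs
    }
    selected = [
        CandidateRecord(m, *pvalues[m], stats=obs[m])
        for m in obs
        if pvalues[m][0] < alpha and pvalues[m][1] < alpha
    ]
    selected.sort(key=lambda c: (-c.stats.nod, -c.stats.tfp, c.mirna_id))
    return CandidateSet(
        condition_label=cond.condition_label,
        candidates=selected,
        alpha=alpha,
        all_stats=stats,
        pvalues=pvalues,
    )
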