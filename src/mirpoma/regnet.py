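"""Condition-specific miRNA-mRNA networks and per-miRNA NOD/TFP statistics.

A condition-specific network is the induced bipartite subgraph of a
reference miRNA->gene network on the differentially expressed miRNAs and
all of their targets.  Within that subgraph, each miRNA m is summarised by

- N: its number of targets (out-degree),
- NOD (novel out degree): the number of its targets regulated by no other
  miRNA in the condition network (target in-degree exactly 1),
- TF: the number of its targets annotated as transcription factors,
- TFP: TF / N.

Uniqueness (NOD) is evaluated within the condition-specific network, so NOD
depends on which miRNAs are differentially expressed, while N, TF and TFP
equal their reference-network values (targets are never pruned).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .data_io import RegulatoryNetwork, ValidationError

log = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (reporting convention; 0.155 -> 0.16 at 2 dp)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MiRNAStats:
    """Per-miRNA network statistics (Table-style columns N, NOD, TF, TFP)."""

    mirna_id: str
    n_targets: int
    nod: int
    tf_targets: int

    def __post_init__(self) -> None:
        if not (0 <= self.nod <= self.n_targets):
            raise ValidationError(f"{self.mirna_id}: NOD {self.nod} > N {self.n_targets}")
        if not (0 <= self.tf_targets <= self.n_targets):
            raise ValidationError(f"{self.mirna_id}: TF {self.tf_targets} > N {self.n_targets}")

    @property
    def tfp(self) -> float:
        """TF-target fraction at full precision (round only when reporting)."""
        return self.tf_targets / self.n_targets

    @property
    def tfp_rounded(self) -> float:
        return round_half_up(self.tfp, 2)


@dataclass
class ConditionNetwork:
    """Induced subnetwork on a condition's DE miRNAs plus bookkeeping."""

    network: RegulatoryNetwork
    condition_label: str

    def __post_init__(self) -> None:
        self._adj = self.network.adjacency()
        self._in_degree = Counter(g for _, g in self.network.edges)

    @property
    def mirnas(self) -> frozenset[str]:
        return self.network.mirnas

    @property
    def genes(self) -> frozenset[str]:
        return self.network.genes

    def targets(self, mirna: str) -> frozenset[str]:
        return frozenset(self._adj[mirna])

    def in_degree(self, gene: str) -> int:
        return self._in_degree[gene]


def build_condition_network(
    reference: RegulatoryNetwork, de_mirnas: frozenset[str] | set[str], label: str
) -> ConditionNetwork:
    """Map DE miRNAs onto the reference network.

    Keeps every reference edge whose miRNA is in the DE set; target genes
    follow their miRNAs, so no orphan genes arise.  DE miRNAs absent from
    the reference are dropped with a logged count; an empty intersection is
    an error.
    """
    retained = frozenset(de_mirnas) & reference.mirnas
    dropped = len(frozenset(de_mirnas)) - len(retained)
    if not retained:
        raise ValidationError(f"{label}: no DE miRNA maps to the reference network")
    if dropped:
        log.info("%s: %d DE miRNA(s) absent from the reference network", label, dropped)
    edges = frozenset((m, g) for m, g in reference.edges if m in retained)
    genes = frozenset(g for _, g in edges)
    sub = RegulatoryNetwork(edges=edges, tf_genes=reference.tf_genes & genes)
    return ConditionNetwork(network=sub, condition_label=label)


def compute_stats(cond: ConditionNetwork) -> list[MiRNAStats]:
    """N, NOD, TF, TFP for every miRNA in the condition network.

    Sorted by non-increasing NOD, ties broken by descending TFP then by ID.
    """
    out = []
    tf = cond.network.tf_genes
    for m in cond.mirnas:
        targets = cond.targets(m)
        nod = sum(1 for g in targets if cond.in_degree(g) == 1)
        out.append(
            MiRNAStats(
                mirna_id=m,
                n_targets=len(targets),
                nod=nod,
                tf_targets=len(targets & tf),
            )
        )
    out.sort(key=lambda s: (-s.nod, -s.tfp, s.mirna_id))
    return out


def unique_targets(cond: ConditionNetwork, mirna: str) -> frozenset[str]:
    """The NOD gene set: targets of ``mirna`` with condition in-degree 1."""
    if mirna not in cond.mirnas:
        raise ValidationError(f"unknown miRNA {mirna!r} in condition {cond.condition_label!r}")
    return frozenset(g for g in cond.targets(mirna) if cond.in_degree(g) == 1)


def stats_table(stats: list[MiRNAStats]) -> pd.DataFrame:
    """Report-ready table with TFP rounded half-up to 2 decimals."""
    return pd.DataFrame(
        {
            "mirna": [s.mirna_id for s in stats],
            "N": [s.n_targets for s in stats],
            "NOD": [s.nod for s in stats],
            "TF": [s.tf_targets for s in stats],
            "TFP": [s.tfp_rounded for s in stats],
        }
    )
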