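"""Synthetic reference networks, expression matrices, gene sets and
literature lists with planted ground truth.

The generators emulate the structure the analysis assumes so that every
stage of the pipeline can be exercised and scored without any download:

- a bipartite miRNA->gene network with truncated-Poisson out-degrees, a
  TF-flagged gene fraction, and a set of *planted* biomarker miRNAs that
  receive private (uniquely targeted) genes and a boosted share of TF
  targets — guaranteeing high NOD and TFP by construction;
- a case/control log2 expression matrix whose per-feature variances follow
  the scaled inverse-chi-square prior the moderated-t estimator assumes,
  with group mean shifts of +/- lfc_magnitude for a chosen DE fraction
  (planted biomarkers are always DE);
- pathway gene sets, optionally enriched for chosen miRNAs' unique targets;
- a literature-style reported-biomarker list mixing true planted
  biomarkers with decoys.

Every generator is a pure function of its arguments including the seed; a
single master seed is split into fixed per-generator substreams.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import (
    CONTROL,
    DISEASE,
    BiomarkerRecord,
    ExpressionMatrix,
    GeneSetCollection,
    GeneSet,
    RegulatoryNetwork,
    ReportedBiomarkerList,
    ValidationError,
)

log = logging.getLogger(__name__)

# fixed substream offsets off the master seed
STREAM_NETWORK = 0
STREAM_EXPRESSION = 1
STREAM_GENESETS = 2
STREAM_REPORTED = 3

#: Default generation parameters: a desk-scale stand-in for a case/control
#: microarray study on a curated target network (hundreds of miRNAs, a few
#: thousand genes, ~10% of genes transcription factors, moderate effect
#: sizes on the log2 scale).
DEFAULTS = dict(
    n_mirna=200,
    n_gene=2000,
    tf_fraction=0.1,
    mean_out_degree=8.0,
    n_planted=10,
    private_targets_per_planted=15,
    planted_tf_boost=0.3,
    n_control=20,
    n_case=20,
    de_fraction=0.3,
    lfc_magnitude=1.5,
    d0=4.0,
    s0sq=0.05,
)


def substream(seed: int, offset: int) -> np.random.Generator:
    """Independent, reproducible child stream of the master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(offset,)))


@dataclass
class SyntheticTruth:
    """Planted ground truth recorded alongside the generated files."""

    planted_biomarkers: frozenset[str]
    de_mirnas: frozenset[str]
    effect_sizes: dict[str, float]
    variance_prior: tuple[float, float] | None  # (d0, s0sq)
    seed: int

    def __post_init__(self) -> None:
        if self.de_mirnas and not self.planted_biomarkers <= self.de_mirnas:
            raise ValidationError("planted biomarkers must be differentially expressed")
        if self.variance_prior is not None:
            d0, s0sq = self.variance_prior
            if d0 <= 0 or s0sq <= 0:
                raise ValidationError("variance prior parameters must be positive")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_biomarkers": sorted(self.planted_biomarkers),
            "de_mirnas": sorted(self.de_mirnas),
            "effect_sizes": {k: self.effect_sizes[k] for k in sorted(self.effect_sizes)},
            "variance_prior": list(self.variance_prior) if self.variance_prior else None,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            planted_biomarkers=frozenset(d["planted_biomarkers"]),
            de_mirnas=frozenset(d["de_mirnas"]),
            effect_sizes=dict(d["effect_sizes"]),
            variance_prior=tuple(d["variance_prior"]) if d["variance_prior"] else None,
            seed=int(d["seed"]),
        )


def _truncated_poisson(rng: np.random.Generator, lam: float) -> int:
    """Poisson(lam) conditioned on >= 1 (rejection; lam > 0)."""
    while True:
        k = int(rng.poisson(lam))
        if k >= 1:
            return k


def simulate_network(
    n_mirna: int = DEFAULTS["n_mirna"],
    n_gene: int = DEFAULTS["n_gene"],
    tf_fraction: float = DEFAULTS["tf_fraction"],
    mean_out_degree: float = DEFAULTS["mean_out_degree"],
    n_planted: int = DEFAULTS["n_planted"],
    private_targets_per_planted: int = DEFAULTS["private_targets_per_planted"],
    planted_tf_boost: float = DEFAULTS["planted_tf_boost"],
    seed: int = 0,
) -> tuple[RegulatoryNetwork, SyntheticTruth]:
    """Generate a bipartite reference network with planted biomarkers.

    Every miRNA draws its out-degree from a Poisson(mean_out_degree)
    truncated at >= 1 and samples targets uniformly from the shared gene
    pool.  Each planted miRNA additionally receives
    ``private_targets_per_planted`` genes targeted by no other miRNA (so its
    full-network NOD is at least that), and a fraction ``planted_tf_boost``
    of its pool targets is drawn from TF genes.
    """
    if n_planted > n_mirna:
        raise ValidationError("n_planted exceeds n_mirna")
    if not (0 <= tf_fraction <= 1 and 0 <= planted_tf_boost <= 1):
        raise ValidationError("tf_fraction and planted_tf_boost must lie in [0, 1]")
    n_private = n_planted * private_targets_per_planted
    if n_private >= n_gene:
        raise ValidationError(
            f"infeasible private-gene demand: {n_private} private genes "
            f"requested from {n_gene} total"
        )
    rng = substream(seed, STREAM_NETWORK)
    mirnas = [f"mir-s{i + 1:03d}" for i in range(n_mirna)]
    genes = np.array([f"g{i + 1:05d}" for i in range(n_gene)])

    tf_genes = set(rng.choice(genes, size=int(round(tf_fraction * n_gene)), replace=False))
    planted = sorted(str(x) for x in rng.choice(mirnas, size=n_planted, replace=False)) if n_planted else []

    reserved = rng.choice(genes, size=n_private, replace=False) if n_private else np.array([])
    pool = np.array(sorted(set(genes) - set(reserved)))
    pool_tf = np.array(sorted(set(pool) & tf_genes))
    pool_nontf = np.array(sorted(set(pool) - tf_genes))

    edges: set[tuple[str, str]] = set()
    planted_set = set(planted)
    private_iter = iter(reserved)
    for m in mirnas:
        k = _truncated_poisson(rng, mean_out_degree)
        if m in planted_set:
            # the TF boost applies to the miRNA's whole target set: top up
            # with TF-gene draws until round(boost * total) of its targets
            # are TFs (private genes count with whatever flag they carry)
            private = {str(next(private_iter)) for _ in range(private_targets_per_planted)}
            total = k + private_targets_per_planted
            want_tf = int(round(planted_tf_boost * total))
            have_tf = sum(1 for g in private if g in tf_genes)
            n_tf = min(max(want_tf - have_tf, 0), pool_tf.size, k)
            chosen = set(private)
            if n_tf:
                chosen |= set(rng.choice(pool_tf, size=n_tf, replace=False))
            n_rest = min(k - n_tf, pool_nontf.size)
            if n_rest > 0:
                chosen |= set(rng.choice(pool_nontf, size=n_rest, replace=False))
        else:
            chosen = set(rng.choice(pool, size=min(k, pool.size), replace=False))
        edges.update((m, str(g)) for g in chosen)

    present_genes = {g for _, g in edges}
    network = RegulatoryNetwork(
        edges=frozenset(edges), tf_genes=frozenset(tf_genes & present_genes)
    )
    truth = SyntheticTruth(
        planted_biomarkers=frozenset(planted),
        de_mirnas=frozenset(planted),
        effect_sizes={},
        variance_prior=None,
        seed=seed,
    )
    return network, truth


def simulate_expression(
    network: RegulatoryNetwork,
    n_control: int = DEFAULTS["n_control"],
    n_case: int = DEFAULTS["n_case"],
    de_fraction: float = DEFAULTS["de_fraction"],
    lfc_magnitude: float = DEFAULTS["lfc_magnitude"],
    d0: float = DEFAULTS["d0"],
    s0sq: float = DEFAULTS["s0sq"],
    seed: int = 0,
    planted_biomarkers: frozenset[str] = frozenset(),
    baseline_mean: float = 7.0,
    baseline_sd: float = 1.0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Case/control log2 expression for the network's miRNAs.

    Per-feature variances are drawn from the scaled inverse-chi-square
    s0sq * d0 / chi2(d0); control samples are Normal(mu_g, sigma_g^2) and
    case samples are shifted by +/- lfc_magnitude for the DE features.
    Planted biomarkers (passed through from the network truth) are always
    DE; with ``lfc_magnitude = 0`` the DE set is empty (pure null).
    """
    if n_control < 2 or n_case < 2:
        raise ValidationError("need >=2 samples per group")
    if not 0 <= de_fraction <= 1:
        raise ValidationError("de_fraction must lie in [0, 1]")
    if d0 <= 0 or s0sq <= 0:
        raise ValidationError("d0 and s0sq must be positive")
    planted = frozenset(planted_biomarkers)
    if not planted <= network.mirnas:
        raise ValidationError("planted biomarkers absent from the network")

    rng = substream(seed, STREAM_EXPRESSION)
    mirnas = sorted(network.mirnas)
    m = len(mirnas)

    sigma2 = s0sq * d0 / rng.chisquare(d0, size=m)
    mu = rng.normal(baseline_mean, baseline_sd, size=m)

    effects: dict[str, float] = {}
    if lfc_magnitude > 0:
        n_de = max(int(round(de_fraction * m)), len(planted))
        non_planted = [x for x in mirnas if x not in planted]
        extra = rng.choice(non_planted, size=max(n_de - len(planted), 0), replace=False)
        de_set = sorted(planted | {str(x) for x in extra})
        signs = rng.choice([-1.0, 1.0], size=len(de_set))
        effects = {mi: float(s * lfc_magnitude) for mi, s in zip(de_set, signs)}

    sd = np.sqrt(sigma2)
    ctrl = rng.normal(mu[:, None], sd[:, None], size=(m, n_control))
    shift = np.array([effects.get(mi, 0.0) for mi in mirnas])
    case = rng.normal((mu + shift)[:, None], sd[:, None], size=(m, n_case))

    samples = [f"ctrl{i + 1:03d}" for i in range(n_control)] + [
        f"case{i + 1:03d}" for i in range(n_case)
    ]
    values = pd.DataFrame(
        np.hstack([ctrl, case]), index=pd.Index(mirnas, name="mirna"), columns=samples
    )
    groups = {s: (CONTROL if s.startswith("ctrl") else DISEASE) for s in samples}
    truth = SyntheticTruth(
        planted_biomarkers=planted if effects else frozenset(),
        de_mirnas=frozenset(effects),
        effect_sizes=effects,
        variance_prior=(d0, s0sq),
        seed=seed,
    )
    return ExpressionMatrix(values=values, groups=groups), truth


def _full_network_unique_targets(network: RegulatoryNetwork) -> dict[str, set[str]]:
    in_deg: dict[str, int] = {}
    for _, g in network.edges:
        in_deg[g] = in_deg.get(g, 0) + 1
    out: dict[str, set[str]] = {m: set() for m in network.mirnas}
    for m, g in network.edges:
        if in_deg[g] == 1:
            out[m].add(g)
    return out


def simulate_gene_sets(
    network: RegulatoryNetwork,
    n_sets: int = 50,
    size_low: int = 20,
    size_high: int = 60,
    n_enriched_for: frozenset[str] = frozenset(),
    enrichment_strength: float = 0.8,
    seed: int = 0,
) -> GeneSetCollection:
    """Pathway gene sets over the network's genes.

    Background sets are uniform draws; for each miRNA in ``n_enriched_for``
    one set draws a fraction ``enrichment_strength`` of its members from
    that miRNA's unique (in-degree-1) targets in the full network, capped
    by availability.
    """
    genes = np.array(sorted(network.genes))
    if not (1 <= size_low <= size_high <= genes.size):
        raise ValidationError("need 1 <= size_low <= size_high <= |genes|")
    enriched_for = sorted(frozenset(n_enriched_for))
    unknown = set(enriched_for) - network.mirnas
    if unknown:
        raise ValidationError(f"unknown miRNA(s) in n_enriched_for: {sorted(unknown)}")
    if len(enriched_for) > n_sets:
        raise ValidationError("more enriched sets requested than n_sets")

    rng = substream(seed, STREAM_GENESETS)
    uniq = _full_network_unique_targets(network)
    sets: dict[str, GeneSet] = {}
    for i, m in enumerate(enriched_for):
        size = int(rng.integers(size_low, size_high + 1))
        pool = np.array(sorted(uniq[m]))
        k = min(int(round(enrichment_strength * size)), pool.size)
        chosen = set(rng.choice(pool, size=k, replace=False)) if k else set()
        rest_pool = np.array(sorted(set(genes) - chosen))
        chosen |= set(rng.choice(rest_pool, size=size - len(chosen), replace=False))
        name = f"enriched_{m}"
        sets[name] = GeneSet(name, f"planted around {m}", frozenset(map(str, chosen)))
    for i in range(n_sets - len(enriched_for)):
        size = int(rng.integers(size_low, size_high + 1))
        chosen = rng.choice(genes, size=size, replace=False)
        name = f"background_{i + 1:03d}"
        sets[name] = GeneSet(name, "background", frozenset(map(str, chosen)))
    return GeneSetCollection(sets=sets)


def simulate_reported_biomarkers(
    truth: SyntheticTruth,
    network: RegulatoryNetwork,
    reported_fraction: float = 0.5,
    n_decoys: int = 10,
    subtype: str = "synthetic",
    seed: int = 0,
) -> ReportedBiomarkerList:
    """A literature-style list: a fraction of the planted biomarkers plus
    decoy miRNAs that the pipeline should not predict."""
    if not 0 <= reported_fraction <= 1:
        raise ValidationError("reported_fraction must lie in [0, 1]")
    rng = substream(seed, STREAM_REPORTED)
    planted = sorted(truth.planted_biomarkers)
    n_true = int(round(reported_fraction * len(planted)))
    true_part = sorted(rng.choice(planted, size=n_true, replace=False)) if n_true else []
    others = sorted(network.mirnas - truth.planted_biomarkers)
    decoys = sorted(rng.choice(others, size=min(n_decoys, len(others)), replace=False))
    records = [
        BiomarkerRecord(m, subtype=subtype, role="diagnostic", direction="unknown")
        for m in true_part
    ] + [BiomarkerRecord(m, subtype=subtype) for m in decoys]
    if not records:
        raise ValidationError("reported list would be empty; raise reported_fraction or n_decoys")
    return ReportedBiomarkerList(records=records)
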