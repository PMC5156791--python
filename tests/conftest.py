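import numpy as np
import pytest

from mirpoma.data_io import RegulatoryNetwork
from mirpoma.regnet import ConditionNetwork


def make_network(adj: dict[str, set[str]], tf_genes: set[str] = frozenset()) -> RegulatoryNetwork:
    """Build a RegulatoryNetwork from a miRNA -> targets mapping."""
    edges = frozenset((m, g) for m, targets in adj.items() for g in targets)
    genes = {g for _, g in edges}
    return RegulatoryNetwork(edges=edges, tf_genes=frozenset(tf_genes) & genes)


def make_condition(adj, tf_genes=frozenset(), label="test") -> ConditionNetwork:
    return ConditionNetwork(network=make_network(adj, tf_genes), condition_label=label)


def random_adjacency(rng: np.random.Generator, n_mirna: int, n_gene: int, p: float):
    """Random bipartite adjacency; every miRNA keeps at least one target."""
    adj = {}
    genes = [f"g{j}" for j in range(n_gene)]
    for i in range(n_mirna):
        mask = rng.random(n_gene) < p
        targets = {g for g, m in zip(genes, mask) if m}
        if not targets:
            targets = {genes[int(rng.integers(n_gene))]}
        adj[f"m{i}"] = targets
    return adj


@pytest.fixture
def toy_condition():
    """Two miRNAs sharing one target; TF on one unique and one shared gene."""
    return make_condition(
        {"m1": {"g1", "g2", "g3"}, "m2": {"g2", "g3", "g4"}},
        tf_genes={"g1", "g4"},
    )
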