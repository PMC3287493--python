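"""Star-threshold filtering, one-level target expansion, and a topology-
preserving random-network null model.

The expansion follows the "drug target expanding network" construction:
each drug's direct targets grow by their one-hop PPI neighbours, and a
protein's cell value becomes the number of times it occurs in that
expansion tree (direct occurrence plus one count per adjacent direct
target). The repeat number acts as an integer weight of the drug-protein
relationship at the network level.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .facts import FactsMatrix
from .io import PPINetwork


def filter_by_stars(net: PPINetwork, min_stars: int) -> PPINetwork:
    """Keep only interactions graded at ``min_stars`` or above.

    The node set shrinks to the endpoints of kept edges ("N Stars UP"
    conditions use the subnetwork, not isolated proteins).
    """
    if not isinstance(min_stars, (int, np.integer)) or not 1 <= min_stars <= 5:
        raise ValueError(f"min_stars must be an integer in 1..5, got {min_stars!r}")
    kept = [(u, v, s) for u, v, s in net.edges() if s >= min_stars]
    return PPINetwork.from_edges(kept)


def expand_one_level(dt: FactsMatrix, net: PPINetwork) -> FactsMatrix:
    """Expand a binary drug-target matrix one level into the PPI network.

    For each drug the expansion multiset contains every direct target once
    plus every PPI neighbour of every direct target; the new cell value is
    the multiplicity of each protein in that multiset. Columns grow to all
    proteins reached by at least one drug. With an empty network the output
    equals the input.
    """
    if not dt.is_binary:
        raise ValueError("expand_one_level expects a binary target matrix")
    per_drug: list[Counter[str]] = []
    for i in range(len(dt.drug_ids)):
        counts: Counter[str] = Counter()
        direct = [dt.feature_ids[j] for j in np.flatnonzero(dt.values[i])]
        for t in direct:
            counts[t] += 1
            for nb in net.neighbors(t):
                counts[nb] += 1
        per_drug.append(counts)
    features = sorted(set().union(*per_drug) if per_drug else set())
    col = {p: j for j, p in enumerate(features)}
    values = np.zeros((len(dt.drug_ids), len(features)), dtype=np.int64)
    for i, counts in enumerate(per_drug):
        for p, c in counts.items():
            values[i, col[p]] = c
    return FactsMatrix(list(dt.drug_ids), features, values, feature_kind="target")


def randomize_network(net: PPINetwork, seed: int) -> PPINetwork:
    """Topology-preserving null network: permute the protein labels.

    The abstract graph (adjacency structure and star grades) is untouched;
    only node identities are shuffled by a seeded uniform permutation, so
    degree and star multisets are preserved exactly while any alignment
    between network neighbourhoods and drug-target placement is destroyed.
    """
    rng = np.random.default_rng(seed)
    nodes = sorted(net.nodes)
    permuted = [nodes[i] for i in rng.permutation(len(nodes))]
    relabel = dict(zip(nodes, permuted))
    edges = [(relabel[u], relabel[v], s) for u, v, s in net.edges()]
    out = PPINetwork.from_edges(edges)
    out.graph.add_nodes_from(permuted)  # keep isolated nodes, if any
    return out
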