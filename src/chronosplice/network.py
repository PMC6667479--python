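"""Cross-set interaction enrichment on labelled interaction networks.

Given a protein–protein interaction network whose nodes carry set labels
(splicing factors, clock-regulated genes, alternatively spliced genes),
this module counts direct interactions between two labelled sets,
calibrates that count against a resampling null (random node sets of the
same size drawn from the network), summarizes cross-degrees, partitions
the network into communities by greedy modularity maximization, and runs
hypergeometric over-representation tests with Benjamini–Hochberg
adjustment.

The empirical p-value uses the add-one rule (1 + #{null >= observed}) /
(n + 1) and therefore can never be zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection, LabelledNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "NullSummary",
    "EnrichmentResult",
    "count_cross_interactions",
    "random_set_null",
    "degree_summary",
    "detect_communities",
    "ora_test",
]


@dataclass
class NullSummary:
    """Resampling null for a cross-set interaction count."""

    n_resamples: int
    observed_count: int
    null_mean: float
    null_sd: float
    empirical_p: float
    null_counts: np.ndarray | None = None


@dataclass
class EnrichmentResult:
    """One gene set's over-representation test result."""

    set_name: str
    overlap_count: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    bh_adjusted_p: float


def _require_label(net: LabelledNetwork, label: str) -> set:
    nodes = net.nodes_with_label(label)
    if not nodes:
        raise ValueError(f"label {label!r} not present in network")
    return nodes


def count_cross_interactions(net: LabelledNetwork, label_a: str, label_b: str) -> int:
    """Number of edges with one endpoint labelled a and the other b.

    An edge whose endpoints each carry both labels still counts once.
    Symmetric in its arguments and independent of input order.
    """
    set_a = _require_label(net, label_a)
    set_b = _require_label(net, label_b)
    count = 0
    for u, v in net.graph.edges:
        if (u in set_a and v in set_b) or (u in set_b and v in set_a):
            count += 1
    return count


def _edges_to_set(graph: nx.Graph, fixed: set, subset: set) -> int:
    count = 0
    for node in subset:
        for nb in graph.adj[node]:
            if nb in fixed:
                count += 1
    # edges with both endpoints in fixed∩subset would be double counted,
    # but subset is drawn from outside the fixed set so this cannot occur
    return count


def random_set_null(
    net: LabelledNetwork,
    fixed_label: str,
    observed_label: str,
    n_resamples: int = 100,
    seed: int | None = None,
    resample_size: int | None = None,
    keep_null_counts: bool = False,
) -> NullSummary:
    """Random-set resampling null for the cross-set interaction count.

    The observed count is the number of edges between the ``fixed_label``
    and ``observed_label`` sets. ``n_resamples`` uniform node subsets of
    ``resample_size`` (default: the number of eligible nodes carrying
    ``observed_label``) are drawn from the universe of all network nodes
    NOT carrying ``fixed_label``; for each, the edges to the fixed set
    are counted. Returns the null mean, SD (n−1 denominator) and the
    add-one empirical p of the observed count.
    """
    fixed = _require_label(net, fixed_label)
    observed = count_cross_interactions(net, fixed_label, observed_label)
    universe = sorted(set(net.graph.nodes) - fixed)
    if resample_size is None:
        resample_size = len(_require_label(net, observed_label) - fixed)
    if resample_size > len(universe):
        raise ValueError(
            f"resample_size {resample_size} exceeds universe of {len(universe)} nodes"
        )
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.empty(n_resamples, dtype=int)
    universe_arr = np.asarray(universe, dtype=object)
    for i in range(n_resamples):
        subset = set(rng.choice(universe_arr, size=resample_size, replace=False))
        counts[i] = _edges_to_set(net.graph, fixed, subset)
    emp_p = (1 + int(np.sum(counts >= observed))) / (n_resamples + 1)
    return NullSummary(
        n_resamples=n_resamples,
        observed_count=observed,
        null_mean=float(counts.mean()),
        null_sd=float(counts.std(ddof=1)) if n_resamples > 1 else 0.0,
        empirical_p=float(emp_p),
        null_counts=counts if keep_null_counts else None,
    )


def degree_summary(net: LabelledNetwork, label_a: str, label_b: str) -> tuple:
    """Mean cross-degree of a-nodes toward b and of b-nodes toward a.

    Both are the cross-edge count divided by the respective set size, so
    mean_a * |a| == mean_b * |b| == cross count. Full precision; round
    only at display.
    """
    set_a = _require_label(net, label_a)
    set_b = _require_label(net, label_b)
    cross = count_cross_interactions(net, label_a, label_b)
    return cross / len(set_a), cross / len(set_b)


def detect_communities(net: LabelledNetwork, seed: int | None = None) -> dict:
    """Partition the network by greedy modularity maximization (CNM-style).

    Each connected component is clustered independently (singleton
    components form their own cluster). Cluster ids are assigned in order
    of decreasing cluster size, then lexicographic smallest member, which
    makes the output deterministic; ``seed`` is accepted for interface
    stability but the greedy procedure itself is deterministic.
    """
    if net.n_nodes == 0:
        raise ValueError("network is empty")
    clusters: list = []
    for comp in nx.connected_components(net.graph):
        sub = net.graph.subgraph(comp)
        if sub.number_of_edges() == 0:
            clusters.append(set(comp))
            continue
        for com in nx.community.greedy_modularity_communities(sub):
            clusters.append(set(com))
    clusters.sort(key=lambda c: (-len(c), min(c)))
    return {node: i for i, c in enumerate(clusters) for node in sorted(c)}


def ora_test(
    query: set, collection: GeneSetCollection, universe: set
) -> list:
    """Hypergeometric over-representation test with BH adjustment.

    For every set S in the collection (intersected with the universe), the
    one-sided upper-tail p  P[X >= |query ∩ S|]  is computed for a
    hypergeometric draw of |query| from the universe. BH is applied across
    all tested sets (including zero-overlap ones). Sorted by p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query) & universe
    names, ps, rows = [], [], []
    for name, members in collection.items():
        members = set(members) & universe
        if not members:
            continue
        overlap = len(query & members)
        # P[X >= overlap]; sf(k-1) is the upper tail including k
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(members), len(query)))
        p = min(1.0, max(p, 0.0))
        names.append(name)
        ps.append(p)
        rows.append((name, overlap, len(members)))
    if not names:
        return []
    adj = multipletests(ps, method="fdr_bh")[1]
    results = [
        EnrichmentResult(
            set_name=name,
            overlap_count=overlap,
            set_size=size,
            query_size=len(query),
            universe_size=len(universe),
            p_value=p,
            bh_adjusted_p=float(min(1.0, max(q, p))),
        )
        for (name, overlap, size), p, q in zip(rows, ps, adj)
    ]
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results
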