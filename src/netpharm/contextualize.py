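"""Random-walk community detection and enrichment-based cluster selection.

Large interaction networks are contextualized to a pathway or tissue by
(1) partitioning the graph with the walktrap algorithm of Pons & Latapy
— short random walks tend to stay trapped inside densely connected
neighbourhoods, so walk-profile distances between nodes expose module
structure — and (2) picking the cluster most enriched (one-tailed
Fisher's exact test) for a reference gene list.

The walktrap implementation follows the original formulation: with
``A`` the adjacency matrix and ``D`` the degree matrix, the t-step
transition matrix is ``P^t = (D^-1 A)^t``; the distance between
communities C1, C2 is

    r(C1, C2)^2 = sum_k (P^t_{C1,k} - P^t_{C2,k})^2 / deg(k)

where ``P^t_{C,k}`` is the mean of the member rows.  At each step the
pair of *adjacent* communities whose merge minimizes the change in the
mean squared distance (the variance criterion
``dsigma = |C1||C2| / (|C1|+|C2|) / n * r^2``) is merged.  The level of
the dendrogram with maximum Newman modularity is reported.  Each
connected component is partitioned independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .exceptions import EmptyNetworkError, NetpharmError, NoSignalError, ParameterError
from .graph import Network, Subnetwork

__all__ = [
    "Partition",
    "EnrichmentResult",
    "walktrap_partition",
    "fisher_enrichment",
    "select_context_cluster",
]


@dataclass
class Partition:
    """Result of a walktrap run at the max-modularity level."""

    assignment: dict[str, int]  # node -> cluster id
    merge_history: list[tuple[int, int, float]]  # per-component merges (ids, dsigma)
    modularity_per_level: list[float]  # whole-graph modularity after k merges
    best_level: int  # number of merges actually applied

    def clusters(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for node, cid in self.assignment.items():
            out.setdefault(cid, set()).add(node)
        return out

    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))


@dataclass
class EnrichmentResult:
    cluster_id: int
    overlap: int
    cluster_size: int
    reference_size: int
    universe_size: int
    p: float


def _walktrap_component(g: nx.Graph, nodes: Sequence[str], steps: int):
    """Run walktrap merges on one connected component.

    Returns (levels, merges): ``levels`` is the list of partitions
    (each a list of frozensets) from all-singletons to one community;
    ``merges`` the (i, j, dsigma) sequence in local community indices.
    """
    nodes = sorted(nodes)
    n = len(nodes)
    if n == 1:
        return [[frozenset(nodes)]], []
    idx = {v: i for i, v in enumerate(nodes)}
    A = nx.to_numpy_array(g, nodelist=nodes)
    deg = A.sum(axis=1)
    P = A / deg[:, None]
    Pt = np.linalg.matrix_power(P, steps)

    # community state: id -> (member frozenset, mean walk profile, size)
    members: dict[int, frozenset] = {i: frozenset([v]) for v, i in idx.items()}
    profile: dict[int, np.ndarray] = {i: Pt[i].copy() for i in range(n)}
    size: dict[int, int] = {i: 1 for i in range(n)}
    # adjacency between communities
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for a, b in g.edges:
        ia, ib = idx[a], idx[b]
        adj[ia].add(ib)
        adj[ib].add(ia)

    inv_deg = 1.0 / deg
    next_id = n
    merges: list[tuple[int, int, float]] = []
    levels: list[list[frozenset]] = [[members[i] for i in sorted(members)]]

    def dsigma(i: int, j: int) -> float:
        diff = profile[i] - profile[j]
        r2 = float(np.dot(diff * diff, inv_deg))
        si, sj = size[i], size[j]
        return si * sj / (si + sj) / n * r2

    while len(members) > 1:
        best = None
        for i in sorted(members):
            for j in sorted(adj[i]):
                if j <= i:
                    continue
                ds = dsigma(i, j)
                key = (ds, min(min(members[i]), min(members[j])),
                       max(min(members[i]), min(members[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        assert best is not None, "component adjacency exhausted prematurely"
        (ds, *_), i, j = best
        k = next_id
        next_id += 1
        members[k] = members[i] | members[j]
        si, sj = size[i], size[j]
        profile[k] = (si * profile[i] + sj * profile[j]) / (si + sj)
        size[k] = si + sj
        adj[k] = (adj[i] | adj[j]) - {i, j}
        for other in adj[k]:
            adj[other].discard(i)
            adj[other].discard(j)
            adj[other].add(k)
        for dead in (i, j):
            del members[dead], profile[dead], size[dead], adj[dead]
        merges.append((i, j, ds))
        levels.append([members[c] for c in sorted(members)])
    return levels, merges


def walktrap_partition(net: Network, steps: int = 4) -> Partition:
    """Partition a network with walktrap (walk length ``steps``).

    Disconnected inputs are partitioned per component and the per-
    component max-modularity levels are combined; isolated nodes form
    singleton clusters.
    """
    if steps < 1:
        raise ParameterError("walktrap steps must be >= 1")
    if net.number_of_nodes() == 0:
        raise EmptyNetworkError("cannot partition an empty network")
    g = net.graph
    assignment: dict[str, int] = {}
    merge_history: list[tuple[int, int, float]] = []
    modularity_per_level: list[float] = []
    best_level_total = 0
    next_cluster = 0
    for comp in sorted(nx.connected_components(g), key=min):
        comp_nodes = sorted(comp)
        sub = g.subgraph(comp_nodes)
        levels, merges = _walktrap_component(sub, comp_nodes, steps)
        if sub.number_of_edges() == 0:
            chosen = levels[0]
            comp_mods = [0.0]
            best = 0
        else:
            comp_mods = [
                nx.community.modularity(sub, level) for level in levels
            ]
            best = int(np.argmax(comp_mods))
            chosen = levels[best]
        merge_history.extend(merges)
        modularity_per_level.extend(comp_mods)
        best_level_total += best
        for cluster in sorted(chosen, key=min):
            for node in cluster:
                assignment[node] = next_cluster
            next_cluster += 1
    return Partition(
        assignment=assignment,
        merge_history=merge_history,
        modularity_per_level=modularity_per_level,
        best_level=best_level_total,
    )


def fisher_enrichment(
    cluster_genes: set[str],
    reference: set[str],
    universe: set[str],
    cluster_id: int = 0,
) -> EnrichmentResult:
    """One-tailed over-representation test (hypergeometric upper tail).

    ``reference`` is intersected with ``universe`` before testing;
    ``cluster_genes`` must already be a subset of the universe.
    """
    if not universe:
        raise NetpharmError("enrichment universe is empty")
    if not cluster_genes <= universe:
        raise NetpharmError("cluster genes must be a subset of the universe")
    ref = reference & universe
    overlap = len(cluster_genes & ref)
    M, K, n = len(universe), len(ref), len(cluster_genes)
    p = float(stats.hypergeom.sf(overlap - 1, M, K, n))
    return EnrichmentResult(
        cluster_id=cluster_id,
        overlap=overlap,
        cluster_size=n,
        reference_size=K,
        universe_size=M,
        p=min(p, 1.0),
    )


def select_context_cluster(
    net: Network,
    partition: Partition,
    reference: set[str],
    name: str = "context",
) -> tuple[Subnetwork, list[EnrichmentResult]]:
    """Pick the cluster most enriched for the reference list.

    Universe = the nodes of the partitioned network.  Ties on p are
    broken by larger overlap, then smaller cluster id.  Returns the
    induced subnetwork and the full enrichment table.
    """
    universe = net.nodes
    reference = {str(g).strip().upper() for g in reference}
    if not reference & universe:
        raise NoSignalError("reference gene list does not intersect the network")
    results = [
        fisher_enrichment(genes, reference, universe, cluster_id=cid)
        for cid, genes in sorted(partition.clusters().items())
    ]
    best = min(results, key=lambda r: (r.p, -r.overlap, r.cluster_id))
    cluster_nodes = partition.clusters()[best.cluster_id]
    return Subnetwork(net, cluster_nodes, name=name), results
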