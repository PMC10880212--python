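"""Graph data model and topological primitives.

All pipelines in this package operate on undirected, unweighted,
simple graphs over gene symbols.  ``Network`` wraps a
:class:`networkx.Graph` and enforces the conventions every downstream
module relies on: symbols are uppercased and whitespace-stripped,
self-loops and duplicate edges are dropped, and edges are unordered
pairs.  ``Subnetwork`` is an induced subgraph that keeps a reference to
its parent, so that distances and diameters can still be taken on the
full background network.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional

import networkx as nx
import pandas as pd

from .exceptions import (
    ConnectivityError,
    EmptyNetworkError,
    EmptySubnetworkError,
    FormatError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "Subnetwork",
    "read_edge_list",
    "write_edge_list",
    "largest_connected_component",
    "graph_diameter",
    "induce_subnetwork",
    "compute_centralities",
]


def normalize_symbol(symbol: str) -> str:
    """Canonical gene-symbol form: stripped and uppercased."""
    return str(symbol).strip().upper()


class Network:
    """Undirected simple graph over gene symbols.

    Parameters
    ----------
    edges:
        Iterable of (gene_a, gene_b) pairs.  Self-loops and duplicate
        edges (in either orientation) are silently dropped.
    nodes:
        Extra nodes to include even if isolated.
    name:
        Label used in logs and output manifests.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        nodes: Iterable[str] = (),
        name: str = "network",
    ):
        g = nx.Graph()
        g.add_nodes_from(normalize_symbol(n) for n in nodes)
        for a, b in edges:
            a, b = normalize_symbol(a), normalize_symbol(b)
            if a == b:
                continue
            g.add_edge(a, b)
        self._graph = g
        self.name = name
        self._diameter: Optional[int] = None

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_networkx(cls, graph: nx.Graph, name: str = "network") -> "Network":
        net = cls(name=name)
        net._graph.add_nodes_from(normalize_symbol(n) for n in graph.nodes)
        net._graph.add_edges_from(
            (normalize_symbol(a), normalize_symbol(b))
            for a, b in graph.edges
            if normalize_symbol(a) != normalize_symbol(b)
        )
        return net

    # -- container protocol ---------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def nodes(self) -> set[str]:
        return set(self._graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self._graph.edges}

    def number_of_nodes(self) -> int:
        return self._graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self._graph.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return normalize_symbol(gene) in self._graph

    def __len__(self) -> int:
        return self.number_of_nodes()

    def __eq__(self, other) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __hash__(self):  # identity hashing; equality is structural
        return id(self)

    def __repr__(self) -> str:
        return (
            f"<{type(self).__name__} {self.name!r}: "
            f"{self.number_of_nodes()} nodes, {self.number_of_edges()} edges>"
        )

    def diameter(self) -> int:
        """Diameter of this network, cached after the first call."""
        if self._diameter is None:
            self._diameter = graph_diameter(self)
        return self._diameter


class Subnetwork(Network):
    """Induced subgraph of a parent :class:`Network`.

    Edges are exactly the parent edges with both endpoints among the
    member nodes; optional per-node scores (e.g. from active-subnetwork
    extraction) ride along.
    """

    def __init__(
        self,
        parent: Network,
        nodes: Iterable[str],
        name: str = "subnetwork",
        node_scores: Optional[Mapping[str, float]] = None,
    ):
        members = {normalize_symbol(n) for n in nodes} & parent.nodes
        super().__init__(name=name)
        self._graph = parent.graph.subgraph(members).copy()
        self.parent = parent
        self.node_scores = dict(node_scores) if node_scores is not None else None


def read_edge_list(
    path,
    format: str = "generic_tsv",
    organism_id: Optional[int] = None,
    name: Optional[str] = None,
) -> Network:
    """Read an undirected edge list from TSV.

    ``generic_tsv`` expects at least two tab-separated columns
    (gene A, gene B); a header line ``gene_a<TAB>gene_b`` and ``#``
    comments are tolerated.  ``biogrid_tab3`` expects the standard
    BioGRID TAB3 header and keeps only rows where both interactor
    organism IDs equal ``organism_id``.
    """
    if format == "generic_tsv":
        edges = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise FormatError(
                        f"{path}:{lineno}: expected >=2 tab-separated columns"
                    )
                a, b = parts[0], parts[1]
                if (a.strip().lower(), b.strip().lower()) == ("gene_a", "gene_b"):
                    continue  # optional header
                edges.append((a, b))
        if not edges:
            raise EmptyNetworkError(f"{path}: no edges after parsing")
        return Network(edges, name=name or "network")

    if format == "biogrid_tab3":
        sym_a = "Official Symbol Interactor A"
        sym_b = "Official Symbol Interactor B"
        org_a = "Organism ID Interactor A"
        org_b = "Organism ID Interactor B"
        try:
            df = pd.read_csv(path, sep="\t", dtype=str, low_memory=False)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise FormatError(f"{path}: cannot parse TAB3 file: {exc}") from exc
        missing = {sym_a, sym_b, org_a, org_b} - set(df.columns)
        if missing:
            raise FormatError(f"{path}: missing TAB3 columns {sorted(missing)}")
        if organism_id is not None:
            keep = (df[org_a].astype(int) == organism_id) & (
                df[org_b].astype(int) == organism_id
            )
            df = df[keep]
        if df.empty:
            raise EmptyNetworkError(
                f"{path}: no interactions left after organism filtering"
            )
        return Network(zip(df[sym_a], df[sym_b]), name=name or "biogrid")

    raise FormatError(f"unknown edge-list format {format!r}")


def write_edge_list(net: Network, path) -> None:
    """Write a network as a sorted two-column TSV (byte-reproducible)."""
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{a}\t{b}\n")


def largest_connected_component(net: Network) -> Subnetwork:
    """Induced subgraph on the largest component.

    Ties on node count are broken by the lexicographically smallest
    member node, so the result is deterministic.
    """
    if net.number_of_nodes() == 0:
        raise EmptyNetworkError("cannot take a component of an empty network")
    components = [set(c) for c in nx.connected_components(net.graph)]
    max_size = max(len(c) for c in components)
    candidates = [c for c in components if len(c) == max_size]
    best = min(candidates, key=lambda c: min(c))
    return Subnetwork(net, best, name=f"{net.name}:lcc")


def graph_diameter(net: Network) -> int:
    """Unweighted diameter (max shortest-path length over node pairs)."""
    if net.number_of_nodes() == 0:
        raise EmptyNetworkError("diameter of an empty network is undefined")
    if net.number_of_nodes() == 1:
        return 0
    if not nx.is_connected(net.graph):
        raise ConnectivityError(
            "diameter requires a connected network; pass the largest component"
        )
    return nx.diameter(net.graph)


def induce_subnetwork(net: Network, genes: Iterable[str], name: str = "induced") -> Subnetwork:
    """Induced subnetwork on ``genes``; absent genes are dropped with a log line."""
    wanted = {normalize_symbol(g) for g in genes}
    present = wanted & net.nodes
    dropped = len(wanted) - len(present)
    if dropped:
        logger.info("induce_subnetwork: dropped %d genes absent from %s", dropped, net.name)
    if not present:
        raise EmptySubnetworkError("no requested genes are present in the network")
    return Subnetwork(net, present, name=name)


def compute_centralities(net: Network) -> pd.DataFrame:
    """Degree, betweenness and closeness centrality per gene.

    Betweenness uses the standard normalization for undirected graphs.
    Closeness is (n-1)/sum(distances) within the node's own component
    (``wf_improved=False``), not the harmonic variant.
    """
    if net.number_of_nodes() == 0:
        raise EmptyNetworkError("centralities of an empty network are undefined")
    g = net.graph
    degree = dict(g.degree())
    betweenness = nx.betweenness_centrality(g, normalized=True)
    closeness = nx.closeness_centrality(g, wf_improved=False)
    df = pd.DataFrame(
        {
            "gene": sorted(g.nodes),
        }
    )
    df["degree"] = df["gene"].map(degree)
    df["betweenness"] = df["gene"].map(betweenness)
    df["closeness"] = df["gene"].map(closeness)
    return df
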