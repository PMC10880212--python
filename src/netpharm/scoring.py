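"""Composite drug-candidate scoring on a background interaction network.

Three complementary views of a candidate's relationship to a disease
subnetwork are combined:

* **network proximity** ``d`` — one minus the diameter-normalized mean,
  over disease-subnetwork nodes, of the minimum shortest-path distance
  to any candidate-subnetwork node;
* **NetSim** — Wang/BMA GO semantic similarity between the two node
  sets (see :mod:`netpharm.go_semsim`);
* **orthogonality** — the negated cosine similarity of the ±1
  deregulation signs over genes common to the two signatures, so a
  candidate that perfectly *reverses* the disease signature scores +1.

The final score is their plain sum, bounded above by 3 and attained
only by a candidate that is on top of the disease subnetwork,
functionally identical and perfectly reversing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import networkx as nx
import pandas as pd

from .dge import GeneSignature
from .exceptions import NetpharmError
from .graph import Network, Subnetwork, largest_connected_component, normalize_symbol
from .go_semsim import GODag, geneset_go_similarity

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreRecord",
    "network_proximity",
    "orthogonality_score",
    "final_score",
    "prioritize",
]


@dataclass
class ScoreRecord:
    """Per-candidate scoring row (the ranking unit)."""

    candidate: str
    d: float
    netsim: float
    cosine: float
    orth: float
    final: float
    n_common: int


def _background_distances(background: Network, targets: set[str]) -> dict[str, int]:
    """Multi-source BFS distances from ``targets`` to every reachable node."""
    return nx.multi_source_dijkstra_path_length(
        background.graph, targets, weight=None
    )


def network_proximity(
    n1_nodes: Iterable[str],
    n2_nodes: Iterable[str],
    background: Network,
    diameter: Optional[int] = None,
) -> float:
    """Diameter-normalized closeness of set N2 to set N1 on the background.

    d = 1 - mean_{n1 in N1} min_{n2 in N2} dist(n1, n2) / Diam.
    Distances are unweighted shortest paths on the background network;
    the diameter is taken on its largest connected component (cached on
    the network).  A source node unreachable from every target
    contributes Diam, i.e. a normalized distance of 1.  The result is
    clipped into [0, 1].
    """
    n1 = {normalize_symbol(g) for g in n1_nodes} & background.nodes
    n2 = {normalize_symbol(g) for g in n2_nodes} & background.nodes
    n_dropped = (len(set(n1_nodes)) - len(n1)) + (len(set(n2_nodes)) - len(n2))
    if n_dropped:
        logger.info("network_proximity: %d genes not in background", n_dropped)
    if not n1 or not n2:
        raise NetpharmError("proximity needs both gene sets to map onto the background")
    if diameter is None:
        if nx.is_connected(background.graph):
            diameter = background.diameter()
        else:
            diameter = largest_connected_component(background).diameter()
    if diameter == 0:
        return 1.0
    dist = _background_distances(background, n2)
    mean_min = sum(min(dist.get(v, diameter), diameter) for v in n1) / len(n1)
    return float(min(1.0, max(0.0, 1.0 - mean_min / diameter)))


def orthogonality_score(
    sig_ref: GeneSignature, sig_cand: GeneSignature
) -> tuple[float, float, int]:
    """Cosine of the ±1 sign vectors over common genes, and its negation.

    Returns (cosine, orth, n_common).  cosine = (n_agree - n_disagree)
    / n_common; orth = -cosine is the reversal-positive term used in
    disease prioritization (a drug opposing every disease sign gets
    orth = +1).  With no common gene both scores are 0.
    """
    common = sig_ref.genes & sig_cand.genes
    if not common:
        return 0.0, 0.0, 0
    agree = sum(1 for g in common if sig_ref.signs[g] == sig_cand.signs[g])
    cosine = (2 * agree - len(common)) / len(common)
    return float(cosine), float(-cosine), len(common)


def final_score(d: float, netsim: float, orth: float) -> float:
    """Sum of the three component scores (maximum attainable value 3)."""
    if not 0.0 <= d <= 1.0:
        raise NetpharmError(f"proximity d out of [0,1]: {d}")
    if not 0.0 <= netsim <= 1.0:
        raise NetpharmError(f"NetSim out of [0,1]: {netsim}")
    if not -1.0 <= orth <= 1.0:
        raise NetpharmError(f"orthogonality out of [-1,1]: {orth}")
    return float(d + netsim + orth)


def prioritize(
    disease_subnet: Subnetwork,
    disease_sig: GeneSignature,
    candidates: Iterable[tuple[str, Network, GeneSignature]],
    background: Network,
    annotations: Mapping[str, frozenset[str]],
    dag: GODag,
    reversal_positive: bool = True,
) -> pd.DataFrame:
    """Score and rank candidate compounds against a disease subnetwork.

    Two orderings are reported: ``rank_d_netsim`` ignores the
    expression direction (proximity + GO similarity only) and
    ``rank_final`` adds the orthogonality term — candidates can and do
    swap places between the two.  Empty candidates are skipped with a
    warning.  Ties break on candidate id.
    """
    if not disease_subnet.nodes <= background.nodes:
        raise NetpharmError("disease subnetwork must live inside the background")
    diameter = (
        background.diameter()
        if nx.is_connected(background.graph)
        else largest_connected_component(background).diameter()
    )
    rows: list[ScoreRecord] = []
    for cand_id, cand_net, cand_sig in candidates:
        if cand_net.number_of_nodes() == 0:
            warnings.warn(f"candidate {cand_id}: empty subnetwork, skipped", stacklevel=2)
            continue
        d = network_proximity(
            disease_subnet.nodes, cand_net.nodes, background, diameter=diameter
        )
        netsim = geneset_go_similarity(
            disease_subnet.nodes, cand_net.nodes, annotations, dag
        )
        cosine, orth, n_common = orthogonality_score(disease_sig, cand_sig)
        third = orth if reversal_positive else cosine
        rows.append(
            ScoreRecord(
                candidate=cand_id,
                d=d,
                netsim=netsim,
                cosine=cosine,
                orth=orth,
                final=final_score(d, netsim, third),
                n_common=n_common,
            )
        )
    if not rows:
        raise NetpharmError("no scorable candidates")
    df = pd.DataFrame([r.__dict__ for r in rows])
    df["d_netsim"] = df["d"] + df["netsim"]
    df = df.sort_values(["final", "candidate"], ascending=[False, True]).reset_index(drop=True)
    df["rank_final"] = range(1, len(df) + 1)
    order_dn = df.sort_values(["d_netsim", "candidate"], ascending=[False, True]).index
    df.loc[order_dn, "rank_d_netsim"] = range(1, len(df) + 1)
    df["rank_d_netsim"] = df["rank_d_netsim"].astype(int)
    return df
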