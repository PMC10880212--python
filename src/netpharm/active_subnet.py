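"""Active-subnetwork extraction from differential-expression p-values.

The node-scoring model is the beta-uniform mixture (BUM): under a null
of no perturbation p-values are Uniform(0,1); signal concentrates near
zero and is captured by a Beta(a, 1) component, giving the density

    f(p) = lambda + (1 - lambda) * a * p^(a-1),   0 < lambda, a < 1.

From a maximum-likelihood fit, a target false-discovery rate is
inverted into a p-value threshold tau, and each gene receives the
(adjusted) log-likelihood-ratio score

    S(p) = (a - 1) * (ln p - ln tau),

positive exactly for p < tau.  The perturbed region of the network is
then the maximum-weight connected subgraph (MWCS) under these scores,
approximated here by a deterministic greedy accretion over "meta-nodes"
(connected components of positive-score nodes) joined through cheapest
negative-score paths.
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
from scipy.optimize import minimize

from .exceptions import InsufficientDataError, ParameterError
from .graph import Network, Subnetwork

__all__ = [
    "BUMFit",
    "NodeScores",
    "fit_bum",
    "fdr_threshold_tau",
    "score_nodes",
    "extract_mwcs",
]

P_FLOOR = 1e-12  # p-values of exactly 0 are clipped here before logs
_GRID = (0.15, 0.5, 0.85)  # fixed 3x3 multi-start grid for (lambda, a)
_BOUND = (1e-6, 1 - 1e-6)


@dataclass
class BUMFit:
    """Maximum-likelihood beta-uniform mixture parameters."""

    lam: float  # uniform mixture weight
    a: float  # beta shape
    loglik: float

    @property
    def pi_upper(self) -> float:
        """Upper bound on the fraction of null p-values: f(1) = lam + (1-lam)a."""
        return self.lam + (1.0 - self.lam) * self.a


@dataclass
class NodeScores:
    """FDR-calibrated node scores; positive iff p < tau."""

    tau: float
    scores: dict[str, float]
    fit: BUMFit

    def min_score(self) -> float:
        return min(self.scores.values())


def _negloglik(params, logp):
    lam, a = params
    # log f(p) with f = lam + (1-lam) * a * p^(a-1), evaluated via logs
    dens = lam + (1.0 - lam) * a * np.exp((a - 1.0) * logp)
    return -float(np.sum(np.log(dens)))


def fit_bum(pvalues) -> BUMFit:
    """Fit the BUM model by bounded multi-start maximum likelihood.

    Deterministic: nine fixed L-BFGS-B starts on a 3x3 grid; best
    log-likelihood wins.  Needs >= 50 p-values for a stable fit.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size < 50:
        raise InsufficientDataError(f"need >=50 p-values to fit BUM, got {p.size}")
    p = np.clip(p, P_FLOOR, 1.0)
    logp = np.log(p)
    best = None
    for lam0 in _GRID:
        for a0 in _GRID:
            res = minimize(
                _negloglik,
                x0=np.array([lam0, a0]),
                args=(logp,),
                method="L-BFGS-B",
                bounds=[_BOUND, _BOUND],
            )
            if best is None or res.fun < best.fun:
                best = res
    lam, a = (float(x) for x in best.x)
    eps = 1e-6
    at_boundary = (
        min(lam - _BOUND[0], _BOUND[1] - lam) <= eps
        and min(a - _BOUND[0], _BOUND[1] - a) <= eps
    )
    if at_boundary:
        warnings.warn(
            "BUM fit degenerate: both parameters at the optimization boundary",
            stacklevel=2,
        )
    return BUMFit(lam=lam, a=a, loglik=-float(best.fun))


def bum_fdr(fit: BUMFit, tau: float) -> float:
    """Model-based FDR of calling p < tau significant."""
    return fit.pi_upper * tau / (fit.lam * tau + (1.0 - fit.lam) * tau**fit.a)


def fdr_threshold_tau(fit: BUMFit, fdr: float = 0.05) -> float:
    """Invert the BUM FDR curve at the requested rate.

    tau = ((pi_upper - fdr*lambda) / (fdr*(1-lambda)))^(1/(a-1)),
    clipped to (0, 1].  If even calling everything significant stays
    under the target rate the threshold saturates at 1.
    """
    if not 0.0 < fdr < 1.0:
        raise ParameterError("fdr must be in (0, 1)")
    num = fit.pi_upper - fdr * fit.lam
    if num <= 0:  # unreachable for valid (lam, a, fdr); kept defensively
        warnings.warn("requested FDR dominated by signal; tau = 1 (all genes pass)",
                      stacklevel=2)
        return 1.0
    tau = (num / (fdr * (1.0 - fit.lam))) ** (1.0 / (fit.a - 1.0))
    if tau >= 1.0:
        warnings.warn("requested FDR exceeds the fitted null fraction; "
                      "tau = 1 (all genes pass)", stacklevel=2)
        return 1.0
    return float(tau)


def score_nodes(pvalues: Mapping[str, float], fit: BUMFit, fdr: float = 0.05) -> NodeScores:
    """Score genes as S(p) = (a-1)(ln p - ln tau) at the FDR threshold."""
    tau = fdr_threshold_tau(fit, fdr)
    scores = {
        gene: (fit.a - 1.0) * (math.log(max(p, P_FLOOR)) - math.log(tau))
        for gene, p in pvalues.items()
    }
    return NodeScores(tau=tau, scores=scores, fit=fit)


def _node_weight(score: float) -> float:
    """Traversal cost of a node: negative scores cost, positive are free."""
    return max(0.0, -score)


def _cheapest_paths(net: Network, scores: Mapping[str, float], selected: set[str]):
    """Multi-source node-weighted Dijkstra out of ``selected``.

    dist[v] = cheapest total weight of non-selected nodes on a path
    from the selected set to v (inclusive of v).  Returns (dist, pred).
    """
    g = net.graph
    dist = {v: math.inf for v in g.nodes}
    pred: dict[str, str | None] = {}
    heap = []
    for v in sorted(selected):
        dist[v] = 0.0
        pred[v] = None
        heapq.heappush(heap, (0.0, v))
    while heap:
        d, v = heapq.heappop(heap)
        if d > dist[v]:
            continue
        for u in sorted(g.neighbors(v)):
            if u in selected:
                continue
            nd = d + _node_weight(scores[u])
            if nd < dist[u] - 1e-15:
                dist[u] = nd
                pred[u] = v
                heapq.heappush(heap, (nd, u))
    return dist, pred


def extract_mwcs(net: Network, node_scores: NodeScores) -> Subnetwork:
    """Greedy maximum-weight connected subgraph under the node scores.

    Deterministic procedure: contract connected components of
    positive-score nodes into meta-nodes (summed score); starting from
    the highest-scoring meta-node, repeatedly attach the meta-node whose
    cheapest connecting path through negative-score nodes leaves the
    largest net gain, while the gain is positive.  Ties break on the
    lexicographically smallest member node.  Genes missing a score are
    assigned the minimum observed score so they can still act as
    connectors.
    """
    if net.number_of_nodes() == 0:
        raise InsufficientDataError("cannot extract a subnetwork from an empty network")
    floor = node_scores.min_score()
    scores = {v: node_scores.scores.get(v, floor) for v in net.nodes}

    positive = {v for v, s in scores.items() if s > 0}
    if not positive:
        warnings.warn("no positive-score node; returning the single best node",
                      stacklevel=2)
        best = min(net.nodes, key=lambda v: (-scores[v], v))
        return Subnetwork(net, {best}, name="active", node_scores={best: scores[best]})

    pos_sub = net.graph.subgraph(positive)
    metas = {}  # meta id (min member) -> (frozenset members, summed score)
    for comp in nx.connected_components(pos_sub):
        comp = frozenset(comp)
        metas[min(comp)] = (comp, sum(scores[v] for v in comp))

    start = min(metas, key=lambda m: (-metas[m][1], m))
    selected = set(metas[start][0])
    remaining = {m for m in metas if m != start}

    while remaining:
        dist, pred = _cheapest_paths(net, scores, selected)
        best_choice = None  # (neg gain, meta id, entry node)
        for m in sorted(remaining):
            members, mscore = metas[m]
            entry = min(
                members, key=lambda v: (dist[v], v)
            )
            cost = dist[entry]
            if math.isinf(cost):
                continue
            gain = mscore - cost
            key = (-gain, m)
            if best_choice is None or key < best_choice[0]:
                best_choice = (key, m, entry)
        if best_choice is None:
            break
        (neg_gain, _), m, entry = best_choice
        if -neg_gain <= 0:
            break
        # add the meta's members plus the connector path back to the old set
        selected |= set(metas[m][0])
        v = pred.get(entry)
        while v is not None:
            selected.add(v)
            v = pred.get(v)
        remaining.discard(m)

    return Subnetwork(
        net, selected, name="active", node_scores={v: scores[v] for v in selected}
    )
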