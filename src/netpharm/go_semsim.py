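"""Wang-method GO term similarity and gene-set similarity (NetSim).

Wang's measure scores two ontology terms by the overlap of their
ancestor closures, with each ancestor's contribution (its "S-value")
decaying multiplicatively along the path: S_A(A) = 1 and, for an
ancestor t of A, S_A(t) = max over edges (c -> t) on paths from A of
w_edge * S_A(c), with w_is_a = 0.8 and w_part_of = 0.6 by default.

    sim(A, B) = sum_{t in T_A ∩ T_B} (S_A(t) + S_B(t)) / (SV(A) + SV(B))

where T_X is X's ancestor closure (X included) and SV(X) = sum of its
S-values.  Gene-gene similarity aggregates the term-pair matrix by
best-match average (BMA), and set-set similarity applies BMA again on
the gene-gene matrix.  The resulting set-level score is the NetSim term
of the final drug-prioritization score and lies in [0, 1].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import obonet

from .exceptions import FormatError, NetpharmError

logger = logging.getLogger(__name__)

__all__ = [
    "GODag",
    "read_obo",
    "read_annotations",
    "wang_term_similarity",
    "geneset_go_similarity",
]

DEFAULT_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}
NAMESPACES = {"biological_process": "BP", "molecular_function": "MF",
              "cellular_component": "CC"}


@dataclass
class GODag:
    """Typed term DAG: child -> parent edges labelled is_a / part_of."""

    namespace: dict[str, str]  # term -> BP/MF/CC
    parents: dict[str, tuple[tuple[str, str], ...]]  # term -> ((parent, rel), ...)

    def __post_init__(self):
        g = nx.DiGraph()
        g.add_nodes_from(self.namespace)
        for child, links in self.parents.items():
            for parent, rel in links:
                if parent not in self.namespace:
                    raise NetpharmError(f"parent term {parent} missing from DAG")
                g.add_edge(child, parent, rel=rel)
        if not nx.is_directed_acyclic_graph(g):
            raise FormatError("ontology contains a cycle")
        self._graph = g

    def __contains__(self, term: str) -> bool:
        return term in self.namespace

    def __len__(self) -> int:
        return len(self.namespace)

    @property
    def roots(self) -> set[str]:
        return {t for t in self.namespace if not self.parents.get(t)}

    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def s_values(self, term: str, weights: Mapping[str, float] = DEFAULT_WEIGHTS) -> dict[str, float]:
        """Max-product S-values over the ancestor closure of ``term``.

        Computed with a Dijkstra-style best-first relaxation: since all
        edge weights are < 1, the first time a term is popped its
        S-value is final.
        """
        if term not in self.namespace:
            raise LookupError(f"unknown ontology term {term}")
        import heapq

        S: dict[str, float] = {}
        heap = [(-1.0, term)]
        while heap:
            negs, t = heapq.heappop(heap)
            if t in S:
                continue
            S[t] = -negs
            for parent, rel in self.parents.get(t, ()):
                w = weights.get(rel)
                if w is None:
                    continue
                cand = S[t] * w
                if cand > S.get(parent, -1.0) and parent not in S:
                    heapq.heappush(heap, (-cand, parent))
        return S


def read_obo(path) -> GODag:
    """Parse an OBO 1.2 flat file (obsolete terms skipped)."""
    graph = obonet.read_obo(path)  # MultiDiGraph, child -> parent, keyed by relation
    namespace: dict[str, str] = {}
    parents: dict[str, list[tuple[str, str]]] = {}
    for term, data in graph.nodes(data=True):
        ns = data.get("namespace", "biological_process")
        namespace[term] = NAMESPACES.get(ns, ns)
        parents.setdefault(term, [])
    for child, parent, rel in graph.edges(keys=True):
        if rel in ("is_a", "part_of"):
            parents.setdefault(child, []).append((parent, rel))
    try:
        return GODag(
            namespace=namespace,
            parents={t: tuple(sorted(ps)) for t, ps in parents.items()},
        )
    except FormatError:
        raise
    except nx.NetworkXError as exc:  # pragma: no cover
        raise FormatError(str(exc)) from exc


def read_annotations(path, dag: GODag) -> dict[str, frozenset[str]]:
    """Read gene -> GO annotations from GAF 2.x or a two-column TSV.

    GAF rows use column 3 (DB Object Symbol) and column 5 (GO ID);
    two-column TSV rows are (gene, term).  Annotations to terms absent
    from the DAG are dropped with a logged count.
    """
    annotations: dict[str, set[str]] = {}
    dropped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("!", "#")):
                continue
            parts = line.split("\t")
            if len(parts) >= 5 and parts[4].startswith("GO:"):
                gene, term = parts[2], parts[4]  # GAF
            elif len(parts) >= 2:
                gene, term = parts[0], parts[1]
            else:
                raise FormatError(f"{path}: unrecognized annotation row: {line!r}")
            gene = gene.strip().upper()
            if term not in dag:
                dropped += 1
                continue
            annotations.setdefault(gene, set()).add(term)
    if dropped:
        logger.info("read_annotations: dropped %d annotations to unknown terms", dropped)
    return {g: frozenset(ts) for g, ts in annotations.items() if ts}


def wang_term_similarity(
    t1: str,
    t2: str,
    dag: GODag,
    weights: Mapping[str, float] = DEFAULT_WEIGHTS,
) -> float:
    """Wang similarity between two terms of the same namespace."""
    if t1 not in dag or t2 not in dag:
        raise LookupError(f"unknown ontology term in pair ({t1}, {t2})")
    if dag.namespace[t1] != dag.namespace[t2]:
        warnings.warn(f"cross-namespace pair ({t1}, {t2}); similarity = 0", stacklevel=2)
        return 0.0
    s1 = dag.s_values(t1, weights)
    s2 = dag.s_values(t2, weights)
    common = set(s1) & set(s2)
    if not common:
        return 0.0
    num = sum(s1[t] + s2[t] for t in common)
    return float(num / (sum(s1.values()) + sum(s2.values())))


def _bma(matrix: np.ndarray) -> float:
    """Best-match average of a non-empty similarity matrix."""
    return float(
        (matrix.max(axis=1).sum() + matrix.max(axis=0).sum())
        / (matrix.shape[0] + matrix.shape[1])
    )


def _gene_gene_similarity(terms1, terms2, dag, weights, cache) -> float:
    mat = np.empty((len(terms1), len(terms2)))
    for i, a in enumerate(terms1):
        for j, b in enumerate(terms2):
            key = (a, b) if a <= b else (b, a)
            if key not in cache:
                cache[key] = wang_term_similarity(a, b, dag, weights)
            mat[i, j] = cache[key]
    return _bma(mat)


def geneset_go_similarity(
    genes1: Iterable[str],
    genes2: Iterable[str],
    annotations: Mapping[str, frozenset[str]],
    dag: GODag,
    namespaces: tuple[str, ...] = ("BP",),
    weights: Mapping[str, float] = DEFAULT_WEIGHTS,
) -> float:
    """Best-match-average GO similarity between two gene sets (NetSim).

    Only annotations in the requested namespaces (biological process by
    default) are used; unannotated genes are dropped with a logged
    count.  If either side has no annotated gene the similarity is 0,
    with a warning, so downstream composite scores stay defined.
    """
    def usable(genes):
        kept = {}
        for g in sorted({str(x).strip().upper() for x in genes}):
            terms = tuple(
                sorted(
                    t for t in annotations.get(g, ())
                    if dag.namespace.get(t) in namespaces
                )
            )
            if terms:
                kept[g] = terms
        return kept

    a1, a2 = usable(genes1), usable(genes2)
    n_in1, n_in2 = len(set(genes1)), len(set(genes2))
    if len(a1) < n_in1 or len(a2) < n_in2:
        logger.info(
            "geneset_go_similarity: %d/%d and %d/%d genes annotated",
            len(a1), n_in1, len(a2), n_in2,
        )
    if not a1 or not a2:
        warnings.warn("no annotated genes on one side; NetSim = 0", stacklevel=2)
        return 0.0
    cache: dict[tuple[str, str], float] = {}
    mat = np.empty((len(a1), len(a2)))
    for i, g1 in enumerate(sorted(a1)):
        for j, g2 in enumerate(sorted(a2)):
            mat[i, j] = _gene_gene_similarity(a1[g1], a2[g2], dag, weights, cache)
    return _bma(mat)
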