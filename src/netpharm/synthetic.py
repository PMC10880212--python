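"""Seeded synthetic fixtures for the whole pipeline.

The generator emulates the statistical structure the pipeline assumes
in real data: a scale-free interactome with a densely connected
perturbed module, gene-level p-values following a beta-uniform mixture
concentrated on that module, ±1 deregulation signs, a small random GO
DAG with leaf-biased gene annotations, and drug signatures whose
overlap with — and sign-reversal of — a disease signature are dialled
by the scenario.  Every operation is driven by a single seeded
generator so that equal seeds give byte-identical fixtures.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np

from .combine import DrugRecord
from .dge import GeneSignature
from .exceptions import ParameterError
from .go_semsim import GODag
from .graph import Network, Subnetwork, largest_connected_component

__all__ = [
    "SyntheticScenario",
    "synth_ppi",
    "synth_module",
    "synth_pvalues",
    "synth_bum_sample",
    "synth_signatures",
    "synth_go",
    "planted_scenario",
    "write_fixture_dir",
]


@dataclass
class SyntheticScenario:
    """Knobs of one synthetic study; defaults are the conditions all
    bundled simulations run under."""

    seed: int = 0
    n_nodes: int = 300
    topology: str = "ba"  # "ba" (scale-free) or "er"
    attachment: int = 2  # BA edges per new node
    edge_prob: float = 0.02  # ER density
    module_size: int = 20
    a_signal: float = 0.05  # beta shape of signal p-values (median ~1e-6)
    lam_true: float = 0.7  # uniform (null) mixture weight
    n_drugs: int = 10
    reversal_fraction: float = 0.5  # rho: shared genes with flipped sign
    overlap_fraction: float = 0.5  # omega: fraction of disease genes shared

    def __post_init__(self):
        if self.module_size > self.n_nodes:
            raise ParameterError("module_size cannot exceed n_nodes")
        for name in ("a_signal", "lam_true", "reversal_fraction", "overlap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def synth_ppi(scenario: SyntheticScenario) -> Network:
    """Scale-free (Barabási–Albert) or Erdős–Rényi graph over synthetic
    gene symbols; the largest connected component is retained."""
    if scenario.n_nodes < 10:
        raise ParameterError("need at least 10 nodes")
    seed = int(np.random.default_rng(scenario.seed).integers(0, 2**31 - 1))
    if scenario.topology == "ba":
        g = nx.barabasi_albert_graph(scenario.n_nodes, scenario.attachment, seed=seed)
    elif scenario.topology == "er":
        g = nx.gnp_random_graph(scenario.n_nodes, scenario.edge_prob, seed=seed)
    else:
        raise ParameterError(f"unknown topology {scenario.topology!r}")
    if g.number_of_edges() == 0:
        raise ParameterError("scenario parameters produced an empty graph")
    names = _gene_names(scenario.n_nodes)
    g = nx.relabel_nodes(g, dict(zip(g.nodes, names)))
    net = Network.from_networkx(g, name=f"synthetic-{scenario.topology}-{scenario.seed}")
    lcc = largest_connected_component(net)
    return Network(lcc.edges, name=net.name)


def synth_module(
    net: Network,
    size: int,
    rng: np.random.Generator,
    density: float = 0.3,
) -> set[str]:
    """Plant a dense module: a BFS ball around a random seed node,
    thickened in place by adding internal edges until the module's edge
    density reaches ``density``.  The planted edges are added to
    ``net`` itself (the module is part of the interactome)."""
    nodes = sorted(net.nodes)
    start = nodes[int(rng.integers(len(nodes)))]
    module = [start]
    seen = {start}
    frontier = [start]
    while len(module) < size and frontier:
        v = frontier.pop(0)
        for u in sorted(net.graph.neighbors(v)):
            if u not in seen:
                seen.add(u)
                module.append(u)
                frontier.append(u)
                if len(module) >= size:
                    break
    module = module[:size]
    pairs = [
        (a, b)
        for i, a in enumerate(module)
        for b in module[i + 1:]
        if not net.graph.has_edge(a, b)
    ]
    n_target = int(density * len(module) * (len(module) - 1) / 2)
    n_add = max(0, n_target - (
        net.graph.subgraph(module).number_of_edges()))
    if pairs and n_add:
        chosen = rng.choice(len(pairs), size=min(n_add, len(pairs)), replace=False)
        net.graph.add_edges_from(pairs[int(i)] for i in chosen)
    return set(module)


def synth_pvalues(
    net: Network,
    module: set[str],
    a_signal: float,
    seed: int,
) -> dict[str, float]:
    """Planted-module p-values: module ~ Beta(a_signal, 1), rest Uniform."""
    if not module <= net.nodes:
        raise ParameterError("module must be a subset of the network nodes")
    rng = np.random.default_rng(seed)
    out = {}
    for gene in sorted(net.nodes):
        if gene in module:
            out[gene] = float(rng.beta(a_signal, 1.0))
        else:
            out[gene] = float(rng.uniform())
    return out


def synth_bum_sample(n: int, lam: float, a: float, seed: int) -> np.ndarray:
    """Direct draws from the beta-uniform mixture (for calibration tests)."""
    rng = np.random.default_rng(seed)
    is_null = rng.uniform(size=n) < lam
    p = np.where(is_null, rng.uniform(size=n), rng.beta(a, 1.0, size=n))
    return np.clip(p, 1e-12, 1.0)


def synth_signatures(
    disease_sig: GeneSignature,
    scenario: SyntheticScenario,
    off_signature_pool: tuple[str, ...] = (),
) -> list[DrugRecord]:
    """Drug signatures with controlled overlap and reversal.

    Each drug shares ceil(omega * |disease_sig|) genes with the disease
    signature; a fraction rho of the shared genes get the opposite
    sign.  Remaining drug genes are drawn from ``off_signature_pool``
    (or synthetic filler symbols) with random signs, so the expected
    sign-cosine against the disease on shared genes is 1 - 2 rho.
    """
    if not disease_sig:
        raise ParameterError("disease signature must be non-empty")
    rng = scenario.rng()
    disease_genes = sorted(disease_sig.genes)
    n_shared = int(np.ceil(scenario.overlap_fraction * len(disease_genes)))
    pool = [g for g in off_signature_pool if g not in disease_sig.genes]
    drugs = []
    for k in range(scenario.n_drugs):
        shared = list(rng.choice(disease_genes, size=n_shared, replace=False)) if n_shared else []
        n_flip = int(round(scenario.reversal_fraction * len(shared)))
        flipped = set(rng.choice(shared, size=n_flip, replace=False)) if n_flip else set()
        signs = {}
        for g in shared:
            signs[g] = -disease_sig.signs[g] if g in flipped else disease_sig.signs[g]
        n_extra = max(0, len(disease_genes) - n_shared)
        if pool and n_extra:
            extras = rng.choice(pool, size=min(n_extra, len(pool)), replace=False)
            for g in extras:
                signs[str(g)] = int(rng.choice([-1, 1]))
        drugs.append(
            DrugRecord(
                drug=f"DRUG{k:03d}",
                dose="1uM",
                signature=GeneSignature(signs=signs, name=f"DRUG{k:03d}"),
            )
        )
    return drugs


def synth_go(
    n_terms: int,
    branching: int,
    n_genes: int,
    seed: int,
    genes: Optional[list[str]] = None,
) -> tuple[GODag, dict[str, frozenset[str]]]:
    """Random rooted BP DAG plus leaf-biased gene annotations.

    Each non-root term attaches to 1–2 earlier terms with is_a edges
    (an occasional part_of); genes get 1–5 annotations biased toward
    the later (deeper) terms.
    """
    if n_terms < 3:
        raise ParameterError("need at least 3 terms")
    rng = np.random.default_rng(seed)
    terms = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    namespace = {t: "BP" for t in terms}
    parents: dict[str, tuple[tuple[str, str], ...]] = {terms[0]: ()}
    for i, t in enumerate(terms[1:], start=1):
        k = int(rng.integers(1, min(2, i) + 1))
        lo = max(0, i - max(branching, 1) * 2)
        choices = rng.choice(np.arange(lo, i), size=k, replace=False)
        links = []
        for j in sorted(int(c) for c in choices):
            rel = "part_of" if rng.uniform() < 0.15 else "is_a"
            links.append((terms[j], rel))
        parents[t] = tuple(links)
    dag = GODag(namespace=namespace, parents=parents)
    if genes is None:
        genes = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    # leaf bias: annotation probability grows linearly with term index
    weights = np.arange(1, n_terms + 1, dtype=float)
    weights /= weights.sum()
    annotations = {}
    for g in genes:
        n_ann = int(rng.integers(1, 6))
        chosen = rng.choice(terms, size=min(n_ann, n_terms), replace=False, p=weights)
        annotations[str(g).strip().upper()] = frozenset(str(t) for t in chosen)
    return dag, annotations


def planted_scenario(seed: int, scenario: Optional[SyntheticScenario] = None) -> dict:
    """A complete prioritization study with one planted winner.

    Builds a scale-free background with a perturbed module, BUM
    p-values, a disease signature over the module, a GO DAG, and
    ``n_drugs`` candidate compounds of which exactly one (its id is
    returned under ``"planted"``) sits on the disease module, shares
    its annotations and reverses every disease sign; the decoys are
    distal, randomly annotated and sign-concordant.
    """
    scenario = scenario or SyntheticScenario(seed=seed, n_nodes=150, module_size=15,
                                             n_drugs=10)
    scenario = dataclasses.replace(scenario, seed=seed)
    rng = scenario.rng()
    net = synth_ppi(scenario)
    module = synth_module(net, min(scenario.module_size, len(net.nodes)), rng)
    pvalues = synth_pvalues(net, module, scenario.a_signal,
                            seed=int(rng.integers(2**31 - 1)))
    disease_nodes = sorted(module)
    disease_sig = GeneSignature(
        signs={g: int(rng.choice([-1, 1])) for g in disease_nodes},
        name="disease",
    )
    dag, annotations = synth_go(
        n_terms=30, branching=2, n_genes=0, seed=int(rng.integers(2**31 - 1)),
        genes=sorted(net.nodes),
    )
    # the planted compound: same nodes, same annotations, perfect reversal
    planted_id = "CAND_PLANTED"
    planted_net = Subnetwork(net, disease_nodes, name=planted_id)
    planted_sig = GeneSignature(
        signs={g: -s for g, s in disease_sig.signs.items()}, name=planted_id
    )
    candidates = [(planted_id, planted_net, planted_sig)]
    distal = sorted(net.nodes - module)
    for k in range(scenario.n_drugs - 1):
        size = max(3, len(disease_nodes) // 2)
        nodes = [str(g) for g in rng.choice(distal, size=size, replace=False)]
        sub = Subnetwork(net, nodes, name=f"CAND{k:02d}")
        shared = [str(g) for g in rng.choice(disease_nodes,
                                             size=max(1, len(disease_nodes) // 3),
                                             replace=False)]
        sig = GeneSignature(
            signs={g: disease_sig.signs[g] for g in shared}, name=f"CAND{k:02d}"
        )
        candidates.append((f"CAND{k:02d}", sub, sig))
    return {
        "scenario": scenario,
        "network": net,
        "module": module,
        "pvalues": pvalues,
        "disease_nodes": disease_nodes,
        "disease_signature": disease_sig,
        "dag": dag,
        "annotations": annotations,
        "candidates": candidates,
        "planted": planted_id,
    }


def _write_obo(dag: GODag, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go\n\n")
        rev_ns = {"BP": "biological_process", "MF": "molecular_function",
                  "CC": "cellular_component"}
        for term in sorted(dag.namespace):
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: synthetic term {term}\n")
            fh.write(f"namespace: {rev_ns.get(dag.namespace[term], dag.namespace[term])}\n")
            for parent, rel in dag.parents.get(term, ()):
                if rel == "is_a":
                    fh.write(f"is_a: {parent} ! synthetic\n")
                else:
                    fh.write(f"relationship: {rel} {parent} ! synthetic\n")
            fh.write("\n")


def write_fixture_dir(scenario: SyntheticScenario, outdir) -> dict[str, Path]:
    """Materialize a full synthetic study as plain-text files.

    Writes the PPI edge list, a DEG table over the network genes, the
    drug signature/known-target tables, an OBO ontology, a gene→term
    annotation TSV and ``scenario.json``.  Every TSV embeds the
    scenario JSON in a ``#`` header comment.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# scenario: {scenario.to_json()}\n"
    rng = scenario.rng()

    net = synth_ppi(scenario)
    module = synth_module(net, min(scenario.module_size, len(net.nodes)), rng)
    pvalues = synth_pvalues(net, module, scenario.a_signal,
                            seed=int(rng.integers(2**31 - 1)))
    paths = {}

    paths["edges"] = outdir / "ppi_edges.tsv"
    with open(paths["edges"], "w") as fh:
        fh.write(header + "gene_a\tgene_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{a}\t{b}\n")

    paths["deg"] = outdir / "deg_table.tsv"
    with open(paths["deg"], "w") as fh:
        fh.write(header + "gene\tlog2fc\tpvalue\n")
        for gene in sorted(net.nodes):
            lfc = float(rng.normal(0, 0.5))
            if gene in module:
                lfc = float(rng.choice([-1, 1]) * rng.uniform(1.5, 3.0))
            fh.write(f"{gene}\t{lfc:.4f}\t{pvalues[gene]:.6g}\n")

    paths["reference"] = outdir / "reference_genes.txt"
    with open(paths["reference"], "w") as fh:
        for gene in sorted(module):
            fh.write(gene + "\n")

    disease_sig = GeneSignature(
        signs={g: int(rng.choice([-1, 1])) for g in sorted(module)}, name="disease"
    )
    drugs = synth_signatures(disease_sig, scenario,
                             off_signature_pool=tuple(sorted(net.nodes - module)))
    paths["drug_signatures"] = outdir / "drug_signatures.tsv"
    with open(paths["drug_signatures"], "w") as fh:
        fh.write(header + "drug\tdose\tgene\tlog2fc\n")
        for drug in drugs:
            for gene in sorted(drug.signature.genes):
                lfc = 2.0 * drug.signature.signs[gene]
                fh.write(f"{drug.drug}\t{drug.dose}\t{gene}\t{lfc:.2f}\n")

    paths["known_targets"] = outdir / "known_targets.tsv"
    with open(paths["known_targets"], "w") as fh:
        fh.write(header + "drug\tgene\n")
        for drug in drugs:
            for gene in sorted(drug.signature.genes)[:2]:
                fh.write(f"{drug.drug}\t{gene}\n")

    dag, annotations = synth_go(30, 2, 0, seed=int(rng.integers(2**31 - 1)),
                                genes=sorted(net.nodes))
    paths["obo"] = outdir / "ontology.obo"
    _write_obo(dag, paths["obo"])
    paths["annotations"] = outdir / "annotations.tsv"
    with open(paths["annotations"], "w") as fh:
        fh.write(header + "# gene\tterm\n")
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                fh.write(f"{gene}\t{term}\n")

    paths["scenario"] = outdir / "scenario.json"
    with open(paths["scenario"], "w") as fh:
        fh.write(scenario.to_json() + "\n")
    return paths
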