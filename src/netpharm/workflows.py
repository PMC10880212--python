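"""End-to-end pipeline runs tying the modules together.

Order of operations mirrors the analysis the package implements:

1. *contextualize*: partition the interactome with walktrap and keep
   the cluster most enriched for a pathway/tissue reference list — this
   becomes the background network.
2. *subnet*: BUM-score differential-expression p-values and extract the
   active subnetwork on the background, then contextualize it again.
3. *prioritize*: score candidate compounds (proximity + NetSim +
   orthogonality) against the disease subnetwork on the background.
4. *combine*: score a drug panel against a chosen compound with the
   disease subnetwork as background and select synergists/enhancers.

Each run writes deterministic, sorted TSV outputs plus a JSON manifest
carrying the configuration hash, so identical configs and inputs give
byte-identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .active_subnet import extract_mwcs, fit_bum, score_nodes
from .combine import (
    build_drug_target_set,
    classify_combinations,
    combination_scores,
    cross_dose_intersection,
)
from .contextualize import select_context_cluster, walktrap_partition
from .dge import GeneSignature, read_deg_table, select_degs
from .exceptions import NetpharmError
from .go_semsim import read_annotations, read_obo
from .graph import Network, Subnetwork, read_edge_list, write_edge_list
from .scoring import prioritize
from .synthetic import SyntheticScenario, write_fixture_dir

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_contextualize", "run_prioritize",
           "run_combine", "run_simulate", "read_gene_list"]


@dataclass
class RunConfig:
    """Declarative configuration; defaults are the pipeline's standard
    constants (FDR 0.05 at both stages, |log2FC| > 1.2, walk length 4,
    50/20 two-stage combination selection)."""

    network: Optional[str] = None
    network_format: str = "generic_tsv"
    organism_id: Optional[int] = None
    reference: Optional[str] = None
    disease_deg: Optional[str] = None
    candidate_degs: dict[str, str] = field(default_factory=dict)
    drug_signatures: Optional[str] = None
    known_targets: Optional[str] = None
    obo: Optional[str] = None
    annotations: Optional[str] = None
    outdir: str = "netpharm_out"

    lfc_min: float = 1.2
    fdr_deg: float = 0.05
    fdr_subnet: float = 0.05
    walktrap_steps: int = 4
    k_rank: int = 50
    k_overlap: int = 20
    reversal_positive_prioritize: bool = True
    combine_score: str = "score_concordant"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def read_gene_list(path) -> set[str]:
    """One symbol per line, or GMT (set name + description + genes)."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) >= 3:  # GMT row
                genes.update(parts[2:])
            else:
                genes.add(parts[0])
    return {g.strip().upper() for g in genes if g.strip()}


def _write_manifest(outdir: Path, config: RunConfig, stage: str, extra: dict) -> None:
    manifest = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "version": __version__,
        **extra,
    }
    with open(outdir / f"{stage}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _contextualize_network(net: Network, reference: set[str], steps: int):
    partition = walktrap_partition(net, steps=steps)
    selected, enrichment = select_context_cluster(net, partition, reference)
    return selected, partition, enrichment


def run_contextualize(config: RunConfig) -> Subnetwork:
    """Walktrap + Fisher selection of the pathway-specific cluster."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net = read_edge_list(config.network, config.network_format, config.organism_id)
    reference = read_gene_list(config.reference)
    selected, partition, enrichment = _contextualize_network(
        net, reference, config.walktrap_steps
    )
    logger.info(
        "contextualize: %d nodes/%d edges -> cluster with %d nodes/%d edges",
        net.number_of_nodes(), net.number_of_edges(),
        selected.number_of_nodes(), selected.number_of_edges(),
    )
    write_edge_list(selected, outdir / "context_network.tsv")
    assign = pd.DataFrame(
        sorted(partition.assignment.items()), columns=["gene", "cluster"]
    )
    best_cluster = min(
        enrichment, key=lambda r: (r.p, -r.overlap, r.cluster_id)
    ).cluster_id
    assign["selected"] = (assign["cluster"] == best_cluster).astype(int)
    assign.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    pd.DataFrame([r.__dict__ for r in enrichment]).to_csv(
        outdir / "enrichment.tsv", sep="\t", index=False
    )
    _write_manifest(outdir, config, "contextualize", {
        "n_input_nodes": net.number_of_nodes(),
        "n_selected_nodes": selected.number_of_nodes(),
    })
    return selected


def _active_subnetwork(
    background: Network, deg: pd.DataFrame, reference: set[str], config: RunConfig,
    name: str,
) -> Subnetwork:
    """BUM scoring + MWCS on the background, then a second contextualization."""
    pvalues = dict(zip(deg["gene"], deg["pvalue"]))
    fit = fit_bum(list(pvalues.values()))
    scores = score_nodes(pvalues, fit, fdr=config.fdr_subnet)
    active = extract_mwcs(background, scores)
    if active.number_of_nodes() > 2:
        refined, _, _ = _contextualize_network(
            active, reference, config.walktrap_steps
        )
        active = Subnetwork(background, refined.nodes, name=name,
                            node_scores={g: active.node_scores[g] for g in refined.nodes})
    logger.info("%s: active subnetwork with %d nodes / %d edges (tau=%.3g)",
                name, active.number_of_nodes(), active.number_of_edges(), scores.tau)
    return active


def run_prioritize(config: RunConfig) -> pd.DataFrame:
    """Full compound prioritization: context -> subnetworks -> ranking."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net = read_edge_list(config.network, config.network_format, config.organism_id)
    reference = read_gene_list(config.reference)
    background, _, _ = _contextualize_network(net, reference, config.walktrap_steps)

    dag = read_obo(config.obo)
    annotations = read_annotations(config.annotations, dag)

    disease_deg = read_deg_table(config.disease_deg)
    disease_subnet = _active_subnetwork(background, disease_deg, reference, config,
                                        "disease")
    disease_sig = select_degs(disease_deg, config.lfc_min, config.fdr_deg,
                              name="disease")

    candidates = []
    for cand_id, path in sorted(config.candidate_degs.items()):
        deg = read_deg_table(path)
        try:
            subnet = _active_subnetwork(background, deg, reference, config, cand_id)
        except NetpharmError as exc:
            logger.warning("candidate %s skipped: %s", cand_id, exc)
            continue
        sig = select_degs(deg, config.lfc_min, config.fdr_deg, name=cand_id)
        candidates.append((cand_id, subnet, sig))

    ranked = prioritize(
        disease_subnet, disease_sig, candidates, background, annotations, dag,
        reversal_positive=config.reversal_positive_prioritize,
    )
    ranked.to_csv(outdir / "prioritization.tsv", sep="\t", index=False)
    write_edge_list(disease_subnet, outdir / "disease_subnetwork.tsv")
    _write_manifest(outdir, config, "prioritize", {
        "n_candidates": len(candidates),
        "background_nodes": background.number_of_nodes(),
        "disease_nodes": disease_subnet.number_of_nodes(),
    })
    return ranked


def _load_drug_records(config: RunConfig) -> list:
    sig = pd.read_csv(config.drug_signatures, sep="\t", comment="#")
    sig.columns = [c.strip().lower() for c in sig.columns]
    known: dict[str, set[str]] = {}
    if config.known_targets:
        kt = pd.read_csv(config.known_targets, sep="\t", comment="#")
        kt.columns = [c.strip().lower() for c in kt.columns]
        for drug, gene in zip(kt["drug"], kt["gene"]):
            known.setdefault(str(drug), set()).add(str(gene))
    records = []
    for (drug, dose), rows in sig.groupby(["drug", "dose"], sort=True):
        rec = build_drug_target_set(
            str(drug),
            list(zip(rows["gene"], rows["log2fc"])),
            known_targets=known.get(str(drug), ()),
            lfc_min=config.lfc_min,
            dose=str(dose),
        )
        if rec is not None:
            records.append(rec)
    return records


def run_combine(
    config: RunConfig,
    disease_background: Network,
    compound_subnet: Network,
    compound_sig: GeneSignature,
) -> pd.DataFrame:
    """Drug-combination scoring and two-stage synergist/enhancer selection."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dag = read_obo(config.obo)
    annotations = read_annotations(config.annotations, dag)
    drugs = _load_drug_records(config)
    table = combination_scores(
        compound_subnet, compound_sig, drugs, disease_background, annotations, dag
    )
    classified = classify_combinations(
        table, k_rank=config.k_rank, k_overlap=config.k_overlap,
        score_col=config.combine_score,
    )
    classified.to_csv(outdir / "combinations.tsv", sep="\t", index=False)
    report = {
        "synergists_all_doses": sorted(cross_dose_intersection(classified, "synergist")),
        "enhancers_all_doses": sorted(cross_dose_intersection(classified, "enhancer")),
        "n_drugs_scored": int(len(classified)),
    }
    with open(outdir / "combination_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    _write_manifest(outdir, config, "combine", report)
    return classified


def run_simulate(config: RunConfig, scenario: Optional[SyntheticScenario] = None):
    """Write a complete synthetic fixture directory."""
    scenario = scenario or SyntheticScenario(seed=config.seed)
    return write_fixture_dir(scenario, Path(config.outdir) / "fixture")
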