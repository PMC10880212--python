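"""Drug-combination simulation against a compound on the disease subnetwork.

The disease target subnetwork becomes the background graph; the
compound subnetwork is the source set and each drug's target set (its
|log2FC|-thresholded signature genes united with its literature
targets) is the target set.  Each drug receives the proximity, NetSim
and sign-cosine components, and an overall score.

Unlike disease prioritization, the combination analysis *wants* drugs
that push common targets in the same direction as the compound, so the
overall score used for the two-stage selection is

    score = d + NetSim + cosine        (concordance convention)

Drugs at the top of this ordering (then filtered to the largest
background-target overlaps) are candidate *synergists*; drugs at the
bottom (typically sharing no targets with the compound) filtered the
same way are *target-network spectrum enhancers*.  The reversal-positive
sum used in disease prioritization is reported alongside.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .dge import GeneSignature
from .exceptions import NetpharmError, ParameterError
from .graph import Network, Subnetwork, largest_connected_component, normalize_symbol
from .go_semsim import GODag, geneset_go_similarity
from .scoring import network_proximity, orthogonality_score

logger = logging.getLogger(__name__)

__all__ = [
    "DrugRecord",
    "build_drug_target_set",
    "combination_scores",
    "select_synergists",
    "select_enhancers",
    "cross_dose_intersection",
]

SYNERGIST = "synergist"
ENHANCER = "enhancer"


@dataclass
class DrugRecord:
    """One (drug, dose) perturbation: signed signature + known targets."""

    drug: str
    dose: str
    signature: GeneSignature
    known_targets: frozenset[str] = frozenset()

    @property
    def target_set(self) -> frozenset[str]:
        return frozenset(self.signature.genes) | self.known_targets

    @property
    def label(self) -> str:
        return f"{self.drug}@{self.dose}" if self.dose else self.drug


def build_drug_target_set(
    drug: str,
    signature_rows: Iterable[tuple[str, float]],
    known_targets: Iterable[str] = (),
    lfc_min: float = 1.2,
    dose: str = "",
) -> Optional[DrugRecord]:
    """Threshold a drug's fold changes and unite with literature targets.

    Genes with |log2FC| > lfc_min keep their sign; known targets
    without an expression change carry no sign (they count for
    proximity and overlap but not for the cosine).  Returns ``None``
    (with a warning) when the combined target set is empty.
    """
    signs, mags = {}, {}
    for gene, lfc in signature_rows:
        gene = normalize_symbol(gene)
        if abs(lfc) > lfc_min:
            signs[gene] = 1 if lfc > 0 else -1
            mags[gene] = abs(lfc)
    known = frozenset(normalize_symbol(g) for g in known_targets)
    record = DrugRecord(
        drug=drug,
        dose=dose,
        signature=GeneSignature(signs=signs, magnitudes=mags, name=f"{drug}@{dose}"),
        known_targets=known,
    )
    if not record.target_set:
        warnings.warn(f"drug {drug}@{dose}: empty target set, skipped", stacklevel=2)
        return None
    return record


def combination_scores(
    compound_subnet: Network,
    compound_sig: GeneSignature,
    drugs: Sequence[DrugRecord],
    disease_background: Network,
    annotations: Mapping[str, frozenset[str]],
    dag: GODag,
) -> pd.DataFrame:
    """Score every drug against the compound on the disease background.

    Drugs with no target mapping onto the background are excluded (and
    logged): their proximity is undefined.  Columns include both the
    concordance-convention overall score (``score_concordant``, used
    for synergist/enhancer selection) and the reversal-positive sum
    (``score_reversal``).
    """
    compound_nodes = compound_subnet.nodes & disease_background.nodes
    n_lost = len(compound_subnet.nodes) - len(compound_nodes)
    if n_lost:
        logger.info("combination_scores: %d compound nodes outside background", n_lost)
    if not compound_nodes:
        raise NetpharmError("compound subnetwork does not map onto the disease background")
    diameter = (
        disease_background.diameter()
        if nx.is_connected(disease_background.graph)
        else largest_connected_component(disease_background).diameter()
    )
    rows = []
    for drug in drugs:
        targets_in_bg = drug.target_set & disease_background.nodes
        if not targets_in_bg:
            logger.info("drug %s: no target in background, excluded", drug.label)
            continue
        d = network_proximity(
            compound_nodes, targets_in_bg, disease_background, diameter=diameter
        )
        netsim = geneset_go_similarity(
            compound_nodes, drug.target_set, annotations, dag
        )
        cosine, orth, n_common = orthogonality_score(compound_sig, drug.signature)
        rows.append(
            {
                "drug": drug.drug,
                "dose": drug.dose,
                "label": drug.label,
                "d": d,
                "netsim": netsim,
                "cosine": cosine,
                "orth": orth,
                "n_common": n_common,
                "overlap_bg": len(targets_in_bg),
                "score_concordant": d + netsim + cosine,
                "score_reversal": d + netsim + orth,
            }
        )
    if not rows:
        raise NetpharmError("no drug has targets on the disease background")
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["score_concordant", "label"], ascending=[False, True]
    ).reset_index(drop=True)


def _two_stage(
    table: pd.DataFrame,
    k_rank: int,
    k_overlap: int,
    ascending: bool,
    score_col: str,
) -> list[str]:
    if k_overlap > k_rank:
        raise ParameterError("k_overlap cannot exceed k_rank")
    if table.empty:
        raise NetpharmError("empty combination table")
    if len(table) < k_rank:
        warnings.warn(
            f"table has {len(table)} drugs < k_rank={k_rank}; using all", stacklevel=3
        )
    stage1 = table.sort_values(
        [score_col, "label"], ascending=[ascending, True]
    ).head(k_rank)
    stage2 = stage1.sort_values(
        ["overlap_bg", "label"], ascending=[False, True]
    ).head(k_overlap)
    return list(stage2["label"])


def select_synergists(
    table: pd.DataFrame,
    k_rank: int = 50,
    k_overlap: int = 20,
    score_col: str = "score_concordant",
) -> list[str]:
    """Top-``k_rank`` drugs by overall score, then the ``k_overlap``
    among them with the most targets on the disease background."""
    return _two_stage(table, k_rank, k_overlap, ascending=False, score_col=score_col)


def select_enhancers(
    table: pd.DataFrame,
    k_rank: int = 50,
    k_overlap: int = 20,
    score_col: str = "score_concordant",
    exclude: Iterable[str] = (),
) -> list[str]:
    """Bottom-``k_rank`` drugs by overall score (synergists removed
    first), then the ``k_overlap`` with the most background targets."""
    exclude = set(exclude)
    remaining = table[~table["label"].isin(exclude)]
    return _two_stage(remaining, k_rank, k_overlap, ascending=True, score_col=score_col)


def classify_combinations(
    table: pd.DataFrame,
    k_rank: int = 50,
    k_overlap: int = 20,
    score_col: str = "score_concordant",
) -> pd.DataFrame:
    """Add a ``class`` column: synergist / enhancer / none (disjoint sets)."""
    synergists = select_synergists(table, k_rank, k_overlap, score_col)
    enhancers = select_enhancers(table, k_rank, k_overlap, score_col, exclude=synergists)
    out = table.copy()
    out["class"] = "none"
    out.loc[out["label"].isin(synergists), "class"] = SYNERGIST
    out.loc[out["label"].isin(enhancers), "class"] = ENHANCER
    return out


def cross_dose_intersection(classified: pd.DataFrame, cls: str = SYNERGIST) -> set[str]:
    """Drugs selected in class ``cls`` at every dose present in the table."""
    doses = classified["dose"].unique()
    per_dose = [
        set(classified[(classified["dose"] == dose) & (classified["class"] == cls)]["drug"])
        for dose in doses
    ]
    return set.intersection(*per_dose) if per_dose else set()
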