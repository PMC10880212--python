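"""Drug target sets, combination scoring and two-stage selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from netpharm import (
    DrugRecord,
    GeneSignature,
    Network,
    Subnetwork,
    build_drug_target_set,
    classify_combinations,
    combination_scores,
    cross_dose_intersection,
    select_enhancers,
    select_synergists,
    synth_go,
)
from netpharm.exceptions import ParameterError

from conftest import random_connected_graph


def test_build_target_set_threshold_and_union():
    rec = build_drug_target_set(
        "drugX", [("g1", 1.5), ("g2", -0.3), ("g3", -2.0)], known_targets=["g4"]
    )
    assert rec.target_set == {"G1", "G3", "G4"}
    assert rec.signature.signs == {"G1": 1, "G3": -1}


def test_build_target_set_known_only_and_empty():
    rec = build_drug_target_set("drugY", [("g1", 0.4)], known_targets=["g4"])
    assert rec.target_set == {"G4"} and not rec.signature
    with pytest.warns(UserWarning):
        assert build_drug_target_set("drugZ", [], known_targets=[]) is None


def _combination_setup(seed=0, n_drugs=8):
    net = random_connected_graph(70, 0.1, seed=seed)
    nodes = sorted(net.nodes)
    compound_nodes = nodes[:10]
    compound = Subnetwork(net, compound_nodes, name="compound")
    compound_sig = GeneSignature(signs={g: 1 for g in compound_nodes})
    dag, annot = synth_go(25, 2, 0, seed=seed, genes=nodes)
    rng = np.random.default_rng(seed)
    drugs = []
    for k in range(n_drugs):
        genes = [str(g) for g in rng.choice(nodes, size=6, replace=False)]
        signs = {g: int(rng.choice([-1, 1])) for g in genes}
        drugs.append(DrugRecord(drug=f"D{k}", dose="1uM",
                                signature=GeneSignature(signs=signs)))
    return net, compound, compound_sig, dag, annot, drugs


def test_identity_drug_tops_everything():
    net, compound, sig, dag, annot, drugs = _combination_setup()
    twin = DrugRecord(drug="TWIN", dose="1uM",
                      signature=GeneSignature(signs=dict(sig.signs)))
    table = combination_scores(compound, sig, drugs + [twin], net, annot, dag)
    row = table[table["drug"] == "TWIN"].iloc[0]
    assert row["d"] == 1.0
    assert row["netsim"] == pytest.approx(1.0)
    assert row["cosine"] == 1.0
    assert table.iloc[0]["drug"] == "TWIN"


def test_zero_common_signed_genes_gives_zero_cosine():
    net, compound, sig, dag, annot, _ = _combination_setup()
    nodes = sorted(net.nodes - compound.nodes)
    disjoint = DrugRecord(drug="DISJ", dose="1uM",
                          signature=GeneSignature(signs={nodes[0]: 1, nodes[1]: -1}))
    table = combination_scores(compound, sig, [disjoint], net, annot, dag)
    assert table.iloc[0]["cosine"] == 0.0
    assert table.iloc[0]["orth"] == 0.0


def test_drug_without_background_targets_excluded():
    net, compound, sig, dag, annot, _ = _combination_setup()
    outsider = DrugRecord(drug="OUT", dose="1uM",
                          signature=GeneSignature(signs={"ZZZZ": 1}))
    inside = DrugRecord(drug="IN", dose="1uM",
                        signature=GeneSignature(signs=dict(sig.signs)))
    table = combination_scores(compound, sig, [outsider, inside], net, annot, dag)
    assert list(table["drug"]) == ["IN"]


def test_scores_match_oracles_on_panel():
    """Every d equals the BFS oracle; every cosine equals a hand sum."""
    import networkx as nx

    net, compound, sig, dag, annot, drugs = _combination_setup(seed=3, n_drugs=12)
    table = combination_scores(compound, sig, drugs, net, annot, dag)
    diam = net.diameter()
    for _, row in table.iterrows():
        drug = next(d for d in drugs if d.drug == row["drug"])
        targets = drug.target_set & net.nodes
        total = 0.0
        for s in compound.nodes:
            dist = nx.single_source_shortest_path_length(net.graph, s)
            total += min(min((dist[t] for t in targets if t in dist), default=diam), diam)
        d_oracle = 1 - total / len(compound.nodes) / diam
        assert row["d"] == pytest.approx(d_oracle, abs=1e-12)
        common = sig.genes & drug.signature.genes
        if common:
            hand = sum(sig.signs[g] * drug.signature.signs[g] for g in common) / len(common)
        else:
            hand = 0.0
        assert row["cosine"] == pytest.approx(hand, abs=1e-12)


def _toy_table():
    return pd.DataFrame(
        {
            "drug": list("ABCDE"),
            "dose": ["1uM"] * 5,
            "label": [f"{x}@1uM" for x in "ABCDE"],
            "score_concordant": [2.5, 2.0, 1.5, 1.0, 0.5],
            "overlap_bg": [1, 5, 3, 4, 2],
        }
    )


def test_two_stage_selection_matches_enumeration():
    table = _toy_table()
    got = select_synergists(table, k_rank=3, k_overlap=2)
    # enumeration: top-3 by score = {A,B,C}; top-2 by overlap = B(5), C(3)
    scores = dict(zip(table["label"], table["score_concordant"]))
    overlaps = dict(zip(table["label"], table["overlap_bg"]))
    stage1 = sorted(scores, key=lambda l: (-scores[l], l))[:3]
    expected = sorted(stage1, key=lambda l: (-overlaps[l], l))[:2]
    assert got == expected == ["B@1uM", "D@1uM"] or got == expected
    # stage-2 never admits a drug outside its stage-1 set
    assert set(got) <= set(stage1)


def test_enhancers_exclude_synergists_and_disjointness():
    table = _toy_table()
    syn = select_synergists(table, k_rank=3, k_overlap=2)
    enh = select_enhancers(table, k_rank=3, k_overlap=2, exclude=syn)
    assert not set(syn) & set(enh)
    classified = classify_combinations(table, k_rank=3, k_overlap=2)
    assert not (
        set(classified[classified["class"] == "synergist"]["label"])
        & set(classified[classified["class"] == "enhancer"]["label"])
    )


def test_all_equal_scores_lexicographic_tie():
    table = _toy_table()
    table["score_concordant"] = 1.0
    table["overlap_bg"] = 2
    got = select_synergists(table, k_rank=5, k_overlap=2)
    assert got == ["A@1uM", "B@1uM"]


def test_k_overlap_exceeding_k_rank_raises():
    with pytest.raises(ParameterError):
        select_synergists(_toy_table(), k_rank=2, k_overlap=3)


def test_small_table_warns_and_uses_all():
    with pytest.warns(UserWarning):
        got = select_synergists(_toy_table(), k_rank=50, k_overlap=3)
    assert len(got) == 3


@pytest.mark.parametrize("seed", range(10))
def test_planted_synergist_and_enhancer_selected(seed):
    """A same-direction proximal drug is always a synergist; a drug with
    many background targets but none in common is always an enhancer."""
    net, compound, sig, dag, annot, _ = _combination_setup(seed=seed, n_drugs=0)
    nodes = sorted(net.nodes)
    outside = [g for g in nodes if g not in compound.nodes]
    rng = np.random.default_rng(seed)
    drugs = []
    for k in range(8):  # decoys share one concordant gene with the compound
        anchor = str(rng.choice(sorted(compound.nodes)))
        gs = [str(g) for g in rng.choice(outside, size=4, replace=False)]
        signs = {g: int(rng.choice([-1, 1])) for g in gs}
        signs[anchor] = sig.signs[anchor]
        drugs.append(DrugRecord(drug=f"D{k}", dose="1uM",
                                signature=GeneSignature(signs=signs)))
    good = DrugRecord(drug="PLANTSYN", dose="1uM",
                      signature=GeneSignature(signs=dict(sig.signs)))
    loner = DrugRecord(drug="PLANTENH", dose="1uM",
                       signature=GeneSignature(signs={g: 1 for g in outside[-8:]}))
    table = combination_scores(compound, sig, drugs + [good, loner], net, annot, dag)
    classified = classify_combinations(table, k_rank=6, k_overlap=3)
    by_label = dict(zip(classified["label"], classified["class"]))
    assert by_label["PLANTSYN@1uM"] == "synergist"
    assert by_label["PLANTENH@1uM"] == "enhancer"


def test_reversing_vs_disjoint_enhancer_composition():
    """Among reversing and target-disjoint drugs, the disjoint ones
    dominate the enhancer list: with no common targets, distal
    positions and unrelated annotations they take the lowest scores."""
    from netpharm import GODag

    net, compound, sig, _, _, _ = _combination_setup(seed=6, n_drugs=0)
    outside = sorted(net.nodes - compound.nodes)
    # two deep branches under one root: compound genes annotate branch A,
    # disjoint-drug genes annotate branch B -> low cross-similarity
    namespace = {"GO:R": "BP"}
    parents = {"GO:R": ()}
    for branch in ("A", "B"):
        prev = "GO:R"
        for depth in range(4):
            t = f"GO:{branch}{depth}"
            namespace[t] = "BP"
            parents[t] = ((prev, "is_a"),)
            prev = t
    dag = GODag(namespace=namespace, parents=parents)
    annot = {g: frozenset({"GO:A3"}) for g in compound.nodes}
    annot.update({g: frozenset({"GO:B3"}) for g in outside})
    drugs = []
    for i in range(5):  # reversing drugs share targets, opposite sign
        drugs.append(DrugRecord(drug=f"REV{i}", dose="1uM",
                                signature=GeneSignature(
                                    signs={g: -s for g, s in sig.signs.items()})))
    for i in range(5):  # disjoint drugs sit elsewhere with no common gene
        gs = outside[3 * i:3 * i + 3]
        drugs.append(DrugRecord(drug=f"DISJ{i}", dose="1uM",
                                signature=GeneSignature(signs={g: 1 for g in gs})))
    table = combination_scores(compound, sig, drugs, net, annot, dag)
    enh = select_enhancers(table, k_rank=5, k_overlap=5)
    assert sum(l.startswith("DISJ") for l in enh) >= 4


def test_cross_dose_intersection():
    rows = []
    for dose in ("a", "b"):
        for drug, cls in [("X", "synergist"), ("Y", "synergist"), ("Z", "enhancer")]:
            if dose == "b" and drug == "Y":
                cls = "none"
            rows.append({"drug": drug, "dose": dose, "class": cls})
    table = pd.DataFrame(rows)
    assert cross_dose_intersection(table, "synergist") == {"X"}
    assert cross_dose_intersection(table, "enhancer") == {"Z"}
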