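"""Simulate drug combinations with a compound on the disease subnetwork.

The disease subnetwork is the background; each drug's target set
(thresholded signature genes + known targets) is scored against the
compound by proximity, NetSim and the sign cosine.  The two-stage rule
takes the top/bottom 50 by overall score, then keeps the 20 with most
targets on the background: concordant proximal drugs are synergist
candidates, disjoint distal ones are target-network spectrum enhancers.
(The toy panel here uses top/bottom 5 then 3.)
"""

import warnings

import numpy as np

from netpharm import (
    DrugRecord,
    GeneSignature,
    Subnetwork,
    SyntheticScenario,
    classify_combinations,
    combination_scores,
    synth_go,
    synth_module,
    synth_ppi,
    synth_signatures,
)

warnings.filterwarnings("ignore")

scenario = SyntheticScenario(seed=5, n_nodes=150, module_size=15, n_drugs=10)
net = synth_ppi(scenario)
module = synth_module(net, 15, scenario.rng())
compound = Subnetwork(net, module, name="compound")
rng = np.random.default_rng(5)
compound_sig = GeneSignature(signs={g: int(rng.choice([-1, 1])) for g in sorted(module)})
dag, annotations = synth_go(25, 2, 0, seed=5, genes=sorted(net.nodes))
pool = tuple(sorted(net.nodes - module))

# a heterogeneous panel: 5 concordant overlapping drugs, 5 with targets
# disjoint from the compound's
import dataclasses

concordant = synth_signatures(
    compound_sig,
    dataclasses.replace(scenario, n_drugs=5, overlap_fraction=0.6,
                        reversal_fraction=0.0),
    off_signature_pool=pool,
)
disjoint = synth_signatures(
    compound_sig,
    dataclasses.replace(scenario, seed=6, n_drugs=5, overlap_fraction=0.0,
                        reversal_fraction=0.0),
    off_signature_pool=pool,
)
drugs = concordant + [
    DrugRecord(drug=f"LONER{i}", dose=d.dose, signature=d.signature)
    for i, d in enumerate(disjoint)
]

table = combination_scores(compound, compound_sig, drugs, net, annotations, dag)
classified = classify_combinations(table, k_rank=5, k_overlap=3)
cols = ["label", "d", "netsim", "cosine", "overlap_bg", "score_concordant", "class"]
print(classified[cols].round(3).to_string(index=False))
syn = classified[classified["class"] == "synergist"]["drug"].tolist()
enh = classified[classified["class"] == "enhancer"]["drug"].tolist()
print(f"\nsynergist candidates: {syn}")
print(f"enhancer candidates:  {enh}")
# score_concordant = d + NetSim + cosine rewards drugs pushing the
# compound's targets in the same direction; the overlap filter then
# keeps drugs that actually engage many background genes.
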