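"""Differentiation signatures from a time course, then pre-ranked GSEA.

A progenitor-to-neuron time course is simulated with 20 rising and 20
falling marker genes; genes consistently up (down) at every neuronal
time point versus day 0 form the "neurons" ("progenitors") signature.
Those signatures are then tested as gene sets against the ranked
LRRK2-vs-healthy list of a cohort in which the neuron markers were also
planted as up-regulated DEGs.
"""

import pandas as pd

from dopasig.diffexp import nb_wald
from dopasig.enrichment import gsea_prerank, make_ranked_list
from dopasig.io import GeneSetCollection
from dopasig.signatures import derive_differentiation_signatures
from dopasig.simulate import (
    SimulationDesign, TIMEPOINTS, simulate_timecourse, study_samples, simulate_counts,
)

counts, labels, truth = simulate_timecourse(
    n_genes=400, n_per_timepoint=4, n_neuron_markers=20,
    n_progenitor_markers=20, effect_size=3.0, seed=3)
results = {}
for tp in TIMEPOINTS[1:]:
    keep = labels["time"].isin(["day0", tp])
    sub_meta = labels.loc[keep].reset_index(drop=True)
    sub = counts.subset_samples(sub_meta["sample_id"])
    results[tp] = nb_wald(sub, sub_meta, ["time"], ("time", tp, "day0"))
neurons, progenitors = derive_differentiation_signatures(results)
print(f"neurons signature: {len(neurons)} genes "
      f"({len(set(neurons.genes) & set(truth.signatures['neurons']))} of 20 planted)")
print(f"progenitors signature: {len(progenitors)} genes")

# cohort where the neuron markers are up-regulated in LRRK2
effects = pd.DataFrame([
    {"gene": g, "factor": "mutation", "level": "LRRK2", "lfc": 1.5}
    for g in neurons.genes])
design = SimulationDesign(n_genes=400, samples=study_samples(),
                          effects=effects, seed=4)
cohort_counts, meta, _ = simulate_counts(design)
de = nb_wald(cohort_counts, meta, ["place", "mutation"],
             ("mutation", "LRRK2", "healthy"))
ranked = make_ranked_list(de)
sets = GeneSetCollection({"neurons": neurons.genes, "progenitors": progenitors.genes})
res = gsea_prerank(ranked, sets, n_perm=1000, seed=5)
print(res[["set", "size", "es", "nes", "pvalue", "fdr"]].to_string(index=False))
# The neurons set should show a strong positive NES (enriched at the top
# of the LRRK2-vs-healthy ranking); progenitors stays near the null.
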