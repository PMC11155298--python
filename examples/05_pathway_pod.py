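"""Pathway over-representation and point-of-departure derivation.

Takes a toy gene-level BMD table, runs the two-tailed Fisher
over-representation test (significant: ≥5 query genes and p < 0.05),
and derives the POD from the most sensitive significant pathways.
"""

import numpy as np
import pandas as pd

from toxpod import GeneSetCollection, derive_pod, enrich_pathways

rng = np.random.default_rng(8)
universe = [f"G{i:03d}" for i in range(400)]
# 60 genes passed all BMD filters; the first 40 concentrate in "pathway_a"
query = universe[:60]
gene_bmds = pd.DataFrame({
    "gene_id": query,
    "bmd": rng.uniform(1, 50, 60),
    "bmdl": rng.uniform(0.5, 10, 60),
    "bmdu": rng.uniform(50, 200, 60),
})
sets = {
    "pathway_a": ("stress response", universe[:50]),
    "pathway_b": ("random background", list(rng.choice(universe, 50, replace=False))),
    "pathway_c": ("tiny overlap", universe[58:120]),
}
coll = GeneSetCollection(sets, universe)

pathways = enrich_pathways(gene_bmds, coll)
print(pathways[["set_name", "n_query_in_set", "fisher_p", "median_bmd",
                "median_bmdl", "significant"]].to_string(index=False))

pod = derive_pod(pathways, chemical="demo", modality="expression")
print(f"\nPOD (BMDL) = {pod.pod_bmdl:.2f} µM via rule '{pod.rule_used}' "
      f"over {pod.n_significant_pathways} significant pathway(s)")
# With fewer than 20 significant pathways the POD falls back to the
# median BMDL across all significant pathways.
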