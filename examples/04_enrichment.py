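"""Genomic-feature and probe-bias-adjusted gene-set enrichment.

A planted odds-2 tilt of the gene-body category among associated loci should
surface as a Fisher odds ratio near 2; the gene-set test uses a Wallenius
noncentral hypergeometric null whose odds correct for genes carrying many
probes.
"""

import methyltraj as mt
from methyltraj.enrichment import results_to_frame

cfg = mt.SimulationConfig(n_probes=20_000, frac_associated=0.05, seed=4)
beta, samples, truth = mt.simulate_beta_dataset(cfg)
ann = mt.simulate_annotation(cfg, truth, region_tilt={"Body": 2.0})

universe = list(ann.index)
res = mt.feature_enrichment(truth.associated_loci, universe, ann, "region_group")
print("genomic-feature enrichment of the (true) signature:")
print(results_to_frame(res).round(4).to_string(index=False))

# gene-set test: a set drawn from signature genes vs a random gene sample
import numpy as np

counts = mt.map_probes_to_genes(universe, ann)
sig_genes = sorted(mt.map_probes_to_genes(truth.associated_loci, ann))
rng = np.random.default_rng(4)
gene_sets = {
    "planted_pathway": list(rng.choice(sig_genes, size=40, replace=False)),
    "random_pathway": list(rng.choice(sorted(counts), size=40, replace=False)),
}
gs = mt.go_enrichment_bias_adjusted(sig_genes, counts, gene_sets)
print("\nbias-adjusted gene-set enrichment:")
print(results_to_frame(gs).round(4).to_string(index=False))
# The tilted gene-body category shows OR ~ 2 with a small p; the set built
# from signature genes ranks far above the random set after FDR correction.
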