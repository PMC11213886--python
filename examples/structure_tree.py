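"""Population structure: LD pruning, PCA, F_ST matrix and NJ tree.

Simulates three diverged populations, prunes linked SNPs, and prints the
leading principal components, the pairwise Weir-Cockerham F_ST matrix and
the neighbour-joining tree built from it.
"""

from capriscan import ldstats, simpop, structure
from capriscan.simpop import SimConfig

cfg = SimConfig(n_pops=3, samples_per_pop=5, ancestral_Ne=100,
                split_generations=40, chrom_length_bp=3_000_000,
                mutation_target_pi=0.002, recomb_rate_cM_Mb=8.0, seed=9)
panel, popmap, _ = simpop.simulate_panel(cfg)
pruned = ldstats.ld_prune(panel, window=50_000, step=10_000, r2_max=0.1)
print(f"pruning kept {pruned.n_variants} of {panel.n_variants} SNPs")

res = structure.pca(pruned, k=4)
print("variance explained (%):", [round(float(x), 2) for x in res.explained_pct])

M = structure.fst_matrix(panel, popmap)
print(M.round(3).to_string())
print("NJ tree:", structure.nj_tree(M))
# Samples of the same population should cluster on PC1/PC2; the tree's
# branch lengths reflect the drift distances in the F_ST matrix.
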