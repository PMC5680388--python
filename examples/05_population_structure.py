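"""Population structure: p-distances + NJ tree, PCA, LD thinning and
pairwise population FST on a simulated three-population cohort.
"""

from sweepherd import (
    SimConfig,
    ld_thin,
    nj_tree,
    pairwise_p_distance,
    pairwise_population_fst,
    pca,
    simulate_cohort,
    split_snps_indels,
)

config = SimConfig(n_populations=3, samples_per_pop=6,
                   chrom_lengths={"chr1": 1_000_000}, fst_bg=0.1, seed=5)
table, popmap, _ = simulate_cohort(config)
snps, _ = split_snps_indels(table)

thinned = ld_thin(snps)  # PLINK indep-pairwise style: 50-SNP window, step 5, r2 > 0.5
print(f"LD thinning kept {thinned.n_sites} of {snps.n_sites} SNPs")

dist = pairwise_p_distance(thinned)
newick = nj_tree(dist)
print("NJ tree (truncated):", newick[:90], "...")

vecs, vals = pca(thinned, k=3)
print("top PCA eigenvalues:", [round(float(v), 2) for v in vals])
print("PC1 range per population (samples should cluster by population):")
for pop in popmap.populations:
    idx = popmap.indices_in(pop, thinned.samples)
    print(f"  {pop}: [{vecs[idx, 0].min():+.3f}, {vecs[idx, 0].max():+.3f}]")

print("\npairwise Weir-Cockerham FST (should be near the simulated F = 0.1):")
print(pairwise_population_fst(snps, popmap).round(3).to_string())
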