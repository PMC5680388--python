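"""Cohort QC summaries: Ti/Tv, het/hom ratios, nucleotide diversity and
cross-population variant sharing.

Ti/Tv near 2.1-2.4 is the mammalian expectation and doubles as a sequencing
quality indicator; theta-pi is the per-bp expected pairwise difference
between two chromosomes of a population.
"""

from sweepherd import (
    SimConfig,
    het_hom_ratio,
    nucleotide_diversity,
    population_sharing,
    simulate_cohort,
    split_snps_indels,
    titv_ratio,
)

config = SimConfig(chrom_lengths={"chr1": 2_000_000}, samples_per_pop=10,
                   n_populations=3, seed=1)
table, popmap, _ = simulate_cohort(config)
snps, _ = split_snps_indels(table)
span = sum(config.chrom_lengths.values())

print(f"Ti/Tv over {snps.n_sites} SNPs: {titv_ratio(snps):.2f}")
for pop, ratio in het_hom_ratio(snps, "population", popmap=popmap).items():
    pi = nucleotide_diversity(snps, pop, span, popmap)
    print(f"{pop}: het/hom = {ratio:.2f}, theta-pi = {pi:.5f} per bp")

sharing = population_sharing(snps, popmap)
print(f"SNPs present in every population: {sharing.shared_by_all} "
      f"({100 * sharing.shared_by_all_fraction:.1f}% of {sharing.total})")
print("population-specific counts:", sharing.population_specific)
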