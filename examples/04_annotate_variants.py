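"""Classify variants by genomic location and coding effect against toy
transcript models (with a consistent reference genome), the way a
resequencing study tabulates exonic / intronic / UTR / intergenic categories
and synonymous / nonsynonymous / stopgain / stoploss / frameshift effects.
"""

from sweepherd import (
    SimConfig,
    annotate_table,
    annotation_summary,
    simulate_cohort,
    simulate_gene_models,
)
from sweepherd.simcohort import harmonize_with_reference

config = SimConfig(chrom_lengths={"chr1": 1_000_000}, samples_per_pop=8, seed=3)
table, _, _ = simulate_cohort(config)
models, genomes = simulate_gene_models(config, genes_per_chrom=25)
harmonize_with_reference(table, genomes, seed=3)  # REF alleles match the FASTA

results = annotate_table(table, models)
summary = annotation_summary(results)
print(summary.to_string(index=False))
print("\nEach variant gets exactly one location category (highest precedence")
print("wins: exonic > splicing > UTR > intronic > up/downstream > intergenic);")
print("effects are reported only for exonic coding variants.")
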