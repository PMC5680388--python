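# Methods

This note documents the models, estimators, parameter choices and known
limitations of `sweepherd`, in the order data flows through the pipeline.

## Hard filtration

The filter reproduces a GATK-style hard-filter protocol for a jointly
called cohort. SNP exclusion: `QD < 2.0`, `ReadPosRankSum < −8.0`,
`FS > 10.0`, `QUAL < 1349.1`, then call rate < 0.7 and MAF < 0.05. Indel
exclusion: the same QD/ReadPosRankSum/FS rules plus two QUAL floors (20.0
and 1257.74 — both applied; the stricter dominates numerically but each
keeps its own removal count), size > 25 bp, and MAF < 0.05. Decisions that
the protocol text leaves open, resolved here and configurable:

* All inequalities are strict, so boundary values (QD exactly 2.0, a 25 bp
  indel) are **kept**.
* `max_missing 0.7` follows the VCFtools convention: keep sites with at
  least 70% called genotypes.
* MAF is cohort-level (all samples jointly), matching a single joint call
  set; it is recomputed from called genotypes only.
* An absent annotation (ReadPosRankSum is emitted conditionally by callers)
  never fails its rule.
* A record failing several rules is attributed to the first failing rule in
  the order quoted above, which makes the per-rule report deterministic and
  reconcilable: survivors + Σ removals = input, and filtering is idempotent.
* Multi-allelic records are skipped (counted), not decomposed: decomposition
  rules are caller-specific and the downstream estimators assume biallelic
  sites.

Two default readings deserve a flag. The MAF cutoff is implemented as 0.05
(a minor-allele frequency *floor*); a cutoff of 0.5 would discard almost
everything and is exposed only as a configurable value. The SNP rule set
has no generic `QUAL < 20` clause while the indel set does; both are
implemented exactly as configured, not harmonized.

## Diversity and QC statistics

Nucleotide diversity uses the unbiased frequency estimator

θπ = Σ_s [n_s/(n_s−1)] · 2 p̂_s (1−p̂_s) / span,

with n_s the called chromosomes of the group at site s. This equals, exactly,
the mean pairwise difference among the sampled chromosomes (the test suite
verifies this identity against brute-force pair enumeration to 1e-12).
Sites with fewer than two called chromosomes are skipped but the span still
covers them; windows therefore compare like with like under missingness.
Ti/Tv counts A↔G and C↔T as transitions. Het/hom is the ratio of
heterozygous to homozygous-alt genotypes (both orientations of the ratio
can be derived; the emitted value is het/hom). A variant is "present" in a
population for sharing purposes when at least one called genotype there
carries an alt allele — the permissive reading appropriate for
"identified in population X", rather than "segregating in X".

## Annotation

Location categories follow the standard gene-based annotation scheme with
precedence exonic > splicing > UTR > intronic > up/downstream > intergenic;
one category per variant, with all transcript-level calls retained in a
detail column. Flank distance 1000 bp and splice window 2 bp are the
conventional defaults and are configurable. Coding effects are computed by
locating the variant's codon through the spliced CDS (strand-aware, alleles
complemented on −), translating ref vs alt codon with the standard genetic
code: stopgain/stoploss take precedence over the synonymous distinction. A
CDS that disagrees with the variant's REF allele, or an incomplete CDS,
yields "unknown" with a warning rather than a silent guess. Indels
overlapping CDS are frameshift when |Δlength| mod 3 ≠ 0. Internal
arithmetic is 0-based half-open; VCF input and reported output are 1-based.

## Population structure

* **p-distance** between individuals is the mean per-allele dosage
  difference over co-called sites, d(i,j) = Σ|g_i − g_j| / (2 m_ij). This is
  a documented convention choice: with unphased genotypes there is no unique
  sequence distance, and the dosage form keeps d in [0, 1] with 0/2
  opposite homozygotes maximally distant.
* **Neighbor joining** is the Saitou–Nei algorithm with the Q criterion;
  ties break toward the lexicographically smallest label pair so output is
  deterministic. The tree is unrooted (trifurcation at the last join);
  with an outgroup the root is placed at the midpoint of the outgroup's
  pendant edge. Additive matrices are reproduced exactly (tests: 1e-9),
  and a generic matrix matches an independent library implementation.
* **PCA** uses the GCTA/Patterson convention: center dosages by 2p̂, scale by
  √(2p̂(1−p̂)), impute missing to the site mean (zero after centering),
  GRM = XXᵀ/m, dense eigendecomposition. Monomorphic sites are dropped.
* **LD** is the genotypic (composite) r²: squared Pearson correlation of
  dosage vectors over co-called samples — the behaviour of PLINK `--r2` on
  unphased data. Pairs with a zero-variance member are skipped and counted.
  Thinning follows `indep-pairwise` semantics on SNP-count windows
  (default 50/5/0.5), removing the later-positioned SNP of an offending
  pair; the survivor set never contains an intra-window pair above the cap.
* **Pairwise population FST** is the genome-wide ratio-of-sums
  Weir–Cockerham estimate per pair.

## The sweep scan

Windows start every `step_bp` (default 10 kb) from 0 while start < chrom
length, truncated at the chromosome end (truncated windows use their
realized span as the θπ denominator), width `window_bp` default 100 kb.
Per-site Weir & Cockerham (1984) two-population variance components are
combined per window as Σa/Σ(a+b+c); sites monomorphic overall or with an
entirely missing population are unusable; windows with fewer than
`min_snps_per_window` (default 10) usable sites are masked. Negative
per-window FST values are retained — clamping would distort the empirical
quantiles. The log2 θπ ratio is masked when the reference diversity is 0,
and −∞ (target 0) is excluded from quantile fitting.

Thresholds are empirical quantiles (linear interpolation between order
statistics — stated because common software defaults differ) of the
unmasked windows, computed independently per statistic: FST uses the right
tail; the ratio uses the right tail under the default `figure4` direction
and the left tail under `depleted`. The default tail is 0.05; the analysis
that motivated this package reported both a "top 10%" rule and 5% tails,
so the fraction is a first-class parameter. The `figure4` direction selects
windows where the target group is *more* diverse (reproducing the published
selection exactly); `depleted` selects the classic sweep signature of lost
target diversity and is what the simulated-recovery benchmarks use.
Selection requires **both** cuts to be exceeded strictly; overlapping or
bookended selected windows merge into candidate regions, and a gene is
attached to a region if ≥ 1 bp of its transcript span overlaps. Whether
published region counts refer to merged or raw windows is unstated in the
protocol this mirrors; merging is this package's documented choice.

## The synthetic cohort

The generator produces the statistical structure the analysis assumes,
with analytic control, rather than a forward/coalescent simulation:

* Site positions are uniform at `mu_density` (default 0.002/bp, matching
  the ≈ 2.2 SNPs/kb genome-wide density typical of a deeply resequenced
  goat cohort).
* Ancestral frequencies follow the neutral SFS, density ∝ 1/p, truncated
  to [maf_floor, 1−maf_floor] (default 0.05) — sites below the floor would
  be removed by the MAF filter anyway.
* Population frequencies are Balding–Nichols: Beta(p(1−F)/F, (1−p)(1−F)/F)
  with F = `fst_bg` (default 0.05), so the realized genome-wide
  Weir–Cockerham estimate converges to F (verified in tests to ±0.015).
* Point mutations are transition-biased (`titv_ratio`, default 2.4), the
  mammalian regime, so Ti/Tv behaves like real data.
* Sweeps: inside each planted interval the site density is divided by
  `sweep_pi_reduction` (default 8) and target-population frequencies are
  pushed toward the nearest fixation by `sweep_freq_shift` (default 0.7),
  jointly depressing target θπ and elevating FST.
* Indels (default 10% of sites, 1–25 bp), i.i.d. missing genotypes
  (default 2%), and site-QC annotations drawn from all-passing
  distributions; `qc_violation_fraction` injects hard-rule violations with
  truth labels, enabling exact filter-count tests.
* One integer seed drives a single generator; identical seeds give
  byte-identical VCFs.

The benchmark cohort (`demo`, and the acceptance script) is 2 populations
× 20 diploids on 2 × 5 Mb chromosomes with two planted 150 kb sweeps
targeting pop1. Sweeps total 3% of the genome — deliberately below the 5%
selection tail, since an empirical-tail threshold cannot flag more of the
genome than its tail fraction; this is a design constraint of
empirical-threshold scans in general, not of the implementation.

What the simulation does **not** emulate: recombination-driven linkage
(sites are exchangeable given their frequencies, so LD decay is flat at the
1/n baseline), mutation-rate heterogeneity, linked background selection,
real genotyping error structure (QC annotations are independent of
genotypes), and realistic gene density. Passing recovery tests therefore
demonstrate estimator and pipeline correctness under the assumed
frequency model, not robustness to haplotype structure — for that, a
coalescent simulator can be substituted as an external input via the same
VCF interface.

## Enrichment

Hypergeometric upper tails are computed by exact summation in log space
(log-gamma binomial coefficients, max-factored), so very small p retain
relative precision; the tests check exhaustive-enumeration agreement at
1e-12 and library agreement. The background defaults to all genes in the
term map ("genome background"); terms with no background member are dropped
before testing, which affects the BH divisor m. BH is the step-up
procedure with q capped at 1 and input order restored. No ontology-graph
propagation is applied — the term map is taken as-is.

## Numerical and degenerate-input policy

* Quantiles: linear interpolation (`numpy` "linear").
* A zero denominator masks rather than errors wherever the quantity is one
  of many (windows, LD pairs); it errors where the result would be the
  whole answer (empty candidate set, no co-called sites for a distance
  pair, monomorphic-only PCA input).
* Undefined ratios (Ti/Tv without transversions, het/hom without hom-alt)
  are NaN-flagged, not zeroed.
* All tie-breaks (NJ pair choice, first-failing-rule attribution, LD
  thinning removal order) are fixed and documented so outputs are
  reproducible byte-for-byte.

## Problem sizes

The default test and demo scale (10 Mb, 40 diploids, ~20k variants) was
chosen so the full suite and the demo each complete in well under a minute
on one CPU while every window/threshold computation still operates in its
asymptotic regime (≥ 1000 windows, ≥ 200 sites per window). All module
parameters accept genome-scale inputs; the windowed statistics are
prefix-sum based and scale linearly in sites + windows.
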