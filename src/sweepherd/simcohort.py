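"""Synthetic multi-population cohort generation.

Builds cohorts with the statistical structure the downstream analyses assume,
so every stage can be exercised and validated without external data:

* background variation with a neutral site-frequency spectrum (density of the
  ancestral allele frequency proportional to 1/p, truncated at ``maf_floor``),
* between-population differentiation under the Balding–Nichols model
  (population frequencies Beta-distributed around the ancestral frequency
  with parameter F = ``fst_bg``, giving analytic control of expected FST),
* planted selective sweeps: inside each sweep interval the site density is
  divided by ``sweep_pi_reduction`` and the target populations' allele
  frequencies are pushed toward fixation by ``sweep_freq_shift``, producing
  locally depressed diversity in the swept group and elevated FST,
* indels of 1..``indel_max_len`` bp, i.i.d. missing genotypes, and site-QC
  annotations (QD, FS, ReadPosRankSum, QUAL, DP) that pass the hard filters
  by default, with labeled filter-violating records injectable on request.

All randomness flows from one integer seed; the same seed yields
byte-identical VCF output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .popmap import PopulationMap
from .varannot import GeneModel, revcomp
from .vcfio import MISSING, VariantTable

BASES = np.array(list("ACGT"))
STOP_CODONS = ("TAA", "TAG", "TGA")
TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS_OF = {"A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G")}


def _draw_alt(ref_base: str, rng, titv: float) -> str:
    """Alt allele under a transition-biased point-mutation model."""
    if rng.random() < titv / (titv + 1.0):
        return TRANSITION_OF[ref_base]
    return TRANSVERSIONS_OF[ref_base][int(rng.integers(0, 2))]


@dataclass(frozen=True)
class SweepInterval:
    """Planted sweep: 0-based half-open interval and its target populations."""

    chrom: str
    start: int
    end: int
    targets: tuple[str, ...]


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults describe the standard benchmark cohort: two populations of 20
    diploids on a 10 Mb genome at ~2 segregating SNPs per kb (matching the
    genome-wide density of a typical goat resequencing call set), background
    differentiation F = 0.05, and strong planted sweeps (8-fold diversity
    reduction, frequency shift 0.7).
    """

    n_populations: int = 2
    samples_per_pop: int = 20
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000})
    mu_density: float = 0.002
    fst_bg: float = 0.05
    sweep_intervals: list[SweepInterval] = field(default_factory=list)
    sweep_pi_reduction: float = 8.0
    sweep_freq_shift: float = 0.7
    titv_ratio: float = 2.4  # transition bias of the point-mutation model
    indel_fraction: float = 0.1
    indel_max_len: int = 25
    missing_rate: float = 0.02
    maf_floor: float = 0.05
    qc_violation_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.sweep_intervals = [
            si if isinstance(si, SweepInterval) else SweepInterval(si[0], si[1], si[2], tuple(si[3]))
            for si in self.sweep_intervals
        ]
        if self.n_populations < 1 or self.samples_per_pop < 1:
            raise ValueError("need at least one population with at least one sample")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.sweep_pi_reduction < 1.0:
            raise ValueError("sweep_pi_reduction must be >= 1")
        if not 0.0 < self.maf_floor < 0.5:
            raise ValueError("maf_floor must be in (0, 0.5)")
        pops = set(self.population_names)
        by_chrom: dict[str, list[SweepInterval]] = {}
        for si in self.sweep_intervals:
            if si.chrom not in self.chrom_lengths:
                raise ValueError(f"sweep interval on unknown chromosome {si.chrom!r}")
            if not 0 <= si.start < si.end <= self.chrom_lengths[si.chrom]:
                raise ValueError(f"sweep interval {si} outside chromosome bounds")
            if not set(si.targets) <= pops:
                raise ValueError(f"sweep targets {si.targets} not among populations")
            by_chrom.setdefault(si.chrom, []).append(si)
        for chrom, sis in by_chrom.items():
            sis = sorted(sis, key=lambda s: s.start)
            for a, b in zip(sis, sis[1:]):
                if a.end > b.start:
                    raise ValueError(f"overlapping sweep intervals on {chrom}")

    @property
    def population_names(self) -> list[str]:
        return [f"pop{i + 1}" for i in range(self.n_populations)]

    @property
    def sample_names(self) -> list[str]:
        return [f"{p}_s{j + 1:02d}" for p in self.population_names for j in range(self.samples_per_pop)]


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort."""

    sweep_intervals: list[SweepInterval]
    realized_pi_ratio: list[float]  # windowed target/non-target diversity ratio per interval
    realized_freq_divergence: list[float]  # mean |p_target - p_other| at interval sites
    qc_violations: list[tuple[str, int, str]] = field(default_factory=list)  # (chrom, pos, rule)


def simulate_cohort(config: SimConfig) -> tuple[VariantTable, PopulationMap, SimTruth]:
    """Generate a cohort; returns (variant table, population map, truth)."""
    rng = np.random.default_rng(config.seed)
    pops = config.population_names
    m = config.samples_per_pop
    n_total = config.n_populations * m
    samples = config.sample_names
    popmap = PopulationMap({s: p for p in pops for s in samples if s.startswith(p + "_")})

    chroms_all, pos_all, ref_all, alt_all = [], [], [], []
    qual_all, qd_all, fs_all, rprs_all, dp_all = [], [], [], [], []
    gt_all, sdp_all = [], []
    pfreq_all: list[np.ndarray] = []  # per-pop drawn frequencies, for truth

    for chrom, L in config.chrom_lengths.items():
        n_draw = rng.poisson(config.mu_density * L)
        pos = np.unique(rng.integers(1, L + 1, size=n_draw))
        # thin sweep intervals: fewer segregating sites inside a sweep
        sweeps = [si for si in config.sweep_intervals if si.chrom == chrom]
        in_sweep = np.zeros(len(pos), dtype=bool)
        for si in sweeps:
            in_sweep |= (pos > si.start) & (pos <= si.end)
        keep = ~in_sweep | (rng.random(len(pos)) < 1.0 / config.sweep_pi_reduction)
        pos = pos[keep]
        in_sweep = in_sweep[keep]
        n = len(pos)

        # ancestral frequency from the truncated neutral SFS (density ~ 1/p)
        a, b = config.maf_floor, 1.0 - config.maf_floor
        p_anc = a * (b / a) ** rng.random(n)

        # Balding-Nichols population frequencies
        F = config.fst_bg
        p_pop = np.empty((config.n_populations, n))
        for k in range(config.n_populations):
            if F <= 0:
                p_pop[k] = p_anc
            else:
                c = (1.0 - F) / F
                p_pop[k] = rng.beta(np.maximum(p_anc * c, 1e-9), np.maximum((1.0 - p_anc) * c, 1e-9))
        # sweep: push target-population frequencies toward the nearest fixation
        for si in sweeps:
            mask = (pos > si.start) & (pos <= si.end)
            for k, p in enumerate(pops):
                if p in si.targets:
                    pk = p_pop[k]
                    shifted = np.where(pk >= 0.5, pk + config.sweep_freq_shift * (1.0 - pk),
                                       pk * (1.0 - config.sweep_freq_shift))
                    p_pop[k] = np.where(mask, shifted, pk)

        genotypes = np.empty((n, n_total), dtype=np.int8)
        for k in range(config.n_populations):
            genotypes[:, k * m:(k + 1) * m] = rng.binomial(2, p_pop[k][:, None], size=(n, m))
        if config.missing_rate > 0:
            genotypes[rng.random((n, n_total)) < config.missing_rate] = MISSING

        # alleles: transition-biased SNPs plus 1..indel_max_len bp indels
        ref_idx = rng.integers(0, 4, size=n)
        ref = BASES[ref_idx].astype(object)
        alt = np.array([_draw_alt(r, rng, config.titv_ratio) for r in ref], dtype=object)
        is_indel = rng.random(n) < config.indel_fraction
        for i in np.flatnonzero(is_indel):
            length = int(rng.integers(1, config.indel_max_len + 1))
            tail = "".join(BASES[rng.integers(0, 4, size=length)])
            if rng.random() < 0.5:
                ref[i], alt[i] = ref[i], ref[i] + tail  # insertion
            else:
                ref[i], alt[i] = ref[i] + tail, ref[i]  # deletion

        # site QC annotations: all-passing by default
        qd = rng.uniform(10.0, 35.0, size=n)
        fs = rng.uniform(0.0, 5.0, size=n)
        rprs = np.clip(rng.normal(0.0, 1.5, size=n), -7.5, 7.5)
        qual = rng.uniform(1500.0, 5000.0, size=n)
        site_dp = rng.poisson(30.0 * n_total, size=n).astype(float)
        sample_dp = rng.poisson(30.0, size=(n, n_total)).astype(np.int32)

        chroms_all.append(np.full(n, chrom, dtype=object))
        pos_all.append(pos)
        ref_all.append(ref)
        alt_all.append(alt)
        qual_all.append(qual)
        qd_all.append(qd)
        fs_all.append(fs)
        rprs_all.append(rprs)
        dp_all.append(site_dp)
        gt_all.append(genotypes)
        sdp_all.append(sample_dp)
        pfreq_all.append(p_pop)

    table = VariantTable(
        np.concatenate(chroms_all), np.concatenate(pos_all),
        np.concatenate(ref_all), np.concatenate(alt_all),
        np.concatenate(qual_all), np.concatenate(qd_all), np.concatenate(fs_all),
        np.concatenate(rprs_all), np.concatenate(dp_all),
        np.concatenate(gt_all, axis=0), samples,
        sample_dp=np.concatenate(sdp_all, axis=0),
        provenance=[{"stage": "simulate", "seed": config.seed}],
    )

    violations = _inject_qc_violations(table, config, rng)
    truth = _build_truth(table, popmap, config, np.concatenate(pfreq_all, axis=1), violations)
    return table, popmap, truth


def _inject_qc_violations(table: VariantTable, config: SimConfig, rng) -> list[tuple[str, int, str]]:
    if config.qc_violation_fraction <= 0:
        return []
    violations = []
    hit = np.flatnonzero(rng.random(table.n_sites) < config.qc_violation_fraction)
    rules = ("qd", "rprs", "fs", "qual")
    for j, i in enumerate(hit):
        rule = rules[j % len(rules)]
        if rule == "qd":
            table.qd[i] = rng.uniform(0.1, 1.9)
        elif rule == "rprs":
            table.rprs[i] = rng.uniform(-20.0, -8.1)
        elif rule == "fs":
            table.fs[i] = rng.uniform(10.1, 50.0)
        else:
            table.qual[i] = rng.uniform(1.0, 19.0)  # fails SNP and both indel floors
        violations.append((table.chrom[i], int(table.pos[i]), rule))
    return violations


def _build_truth(table, popmap, config, p_pop, violations) -> SimTruth:
    from .varstats import per_site_pi

    pops = config.population_names
    ratios, divergences = [], []
    for si in config.sweep_intervals:
        mask = (table.chrom == si.chrom) & (table.pos > si.start) & (table.pos <= si.end)
        span = si.end - si.start
        t_idx = [i for p in si.targets for i in popmap.indices_in(p, table.samples)]
        o_idx = [i for p in pops if p not in si.targets for i in popmap.indices_in(p, table.samples)]
        sub = table.subset(mask)
        pi_t = per_site_pi(sub, t_idx).sum() / span
        pi_o = per_site_pi(sub, o_idx).sum() / span if o_idx else float("nan")
        ratios.append(float(pi_t / pi_o) if pi_o and np.isfinite(pi_o) else float("nan"))
        tk = [k for k, p in enumerate(pops) if p in si.targets]
        ok = [k for k, p in enumerate(pops) if p not in si.targets]
        if ok and mask.any():
            dv = np.abs(p_pop[tk][:, mask].mean(axis=0) - p_pop[ok][:, mask].mean(axis=0)).mean()
        else:
            dv = float("nan")
        divergences.append(float(dv))
    return SimTruth(list(config.sweep_intervals), ratios, divergences, violations)


# ---------------------------------------------------------------------------
# gene models + reference


def simulate_gene_models(
    config: SimConfig,
    genes_per_chrom: int = 3,
    noncoding_fraction: float = 0.2,
) -> tuple[list[GeneModel], dict[str, str]]:
    """Emit toy transcript models and a consistent reference genome.

    Transcripts are non-overlapping, on both strands, with UTR5/CDS/intron/
    UTR3 block structure; every coding CDS begins ATG, ends with a stop codon
    and contains no internal stop. A ``noncoding_fraction`` of transcripts is
    emitted as ncRNA (no CDS). Returns (models, {chrom: sequence}).
    """
    rng = np.random.default_rng([config.seed, 90_001])
    models: list[GeneModel] = []
    genomes: dict[str, str] = {}
    gene_no = 0
    for chrom, L in config.chrom_lengths.items():
        seq = BASES[rng.integers(0, 4, size=L)]
        slot = L // (genes_per_chrom + 1)
        if slot < 10_000:
            raise ValueError(f"chromosome {chrom} too short for {genes_per_chrom} transcripts")
        for g in range(genes_per_chrom):
            gene_no += 1
            start = slot * g + slot // 2 + int(rng.integers(0, 1000))
            strand = "+" if rng.random() < 0.5 else "-"
            coding = rng.random() >= noncoding_fraction
            model, spliced_plus, gpos = _build_transcript(
                rng, chrom, start, strand, coding, f"GENE{gene_no:03d}", f"TX{gene_no:03d}"
            )
            seq[gpos] = np.array(list(spliced_plus))
            models.append(model)
        genomes[chrom] = "".join(seq)
    return models, genomes


def _build_transcript(rng, chrom, start, strand, coding, gene_id, tx_id):
    n_exons = int(rng.integers(1, 5))
    u5 = int(rng.integers(30, 120))
    n_codons = int(rng.integers(60, 200))
    u3 = int(rng.integers(30, 120))
    if coding:
        codons = ["ATG"]
        sense = [c for c in ("".join(t) for t in _all_codons()) if c not in STOP_CODONS and c != "ATG"]
        codons += [sense[int(rng.integers(0, len(sense)))] for _ in range(n_codons - 2)]
        codons.append(STOP_CODONS[int(rng.integers(0, 3))])
        cds = "".join(codons)
    else:
        cds = ""
    utr5 = "".join(BASES[rng.integers(0, 4, size=u5)])
    utr3 = "".join(BASES[rng.integers(0, 4, size=u3)])
    spliced = utr5 + cds + utr3
    total = len(spliced)

    # split the spliced sequence over exons separated by introns
    cuts = sorted(rng.choice(np.arange(1, total), size=n_exons - 1, replace=False).tolist()) if n_exons > 1 else []
    bounds = [0] + cuts + [total]
    exon_lens = [bounds[i + 1] - bounds[i] for i in range(n_exons)]
    intron_lens = [int(rng.integers(60, 400)) for _ in range(n_exons - 1)]
    exons = []
    gcursor = start
    for i, el in enumerate(exon_lens):
        exons.append((gcursor, gcursor + el))
        gcursor += el + (intron_lens[i] if i < len(intron_lens) else 0)
    gpos = np.concatenate([np.arange(s, e) for s, e in exons])

    spliced_plus = spliced if strand == "+" else revcomp(spliced)
    if coding:
        if strand == "+":
            lo, hi = u5, u5 + len(cds)
        else:
            lo, hi = total - (u5 + len(cds)), total - u5
        cds_start, cds_end = int(gpos[lo]), int(gpos[hi - 1]) + 1
    else:
        cds_start = cds_end = int(gpos[0])
    model = GeneModel(
        gene_id=gene_id, transcript_id=tx_id, chrom=chrom, strand=strand,
        exons=exons, cds_start=cds_start, cds_end=cds_end,
        cds_seq=cds if coding else None,
    )
    return model, spliced_plus, gpos


def _all_codons():
    from itertools import product

    return product("ACGT", repeat=3)


def harmonize_with_reference(table: VariantTable, genomes: dict[str, str],
                             seed: int = 0, titv_ratio: float = 2.4) -> None:
    """Rewrite REF alleles to match a reference genome, in place.

    SNP REF becomes the reference base (ALT redrawn, transition-biased, to
    differ); indels keep their length but anchor on the reference base.
    Genotypes are untouched.
    """
    rng = np.random.default_rng([seed, 31_337])
    for i in range(table.n_sites):
        base = genomes[table.chrom[i]][int(table.pos[i]) - 1]
        ref, alt = table.ref[i], table.alt[i]
        if len(ref) == 1 and len(alt) == 1:
            table.ref[i] = base
            table.alt[i] = _draw_alt(base, rng, titv_ratio)
        else:
            table.ref[i] = base + ref[1:]
            table.alt[i] = base + alt[1:]


# ---------------------------------------------------------------------------
# truth + FASTA I/O


def write_truth(truth: SimTruth, path: str | Path) -> None:
    """Planted sweep intervals as BED (0-based half-open); name = targets."""
    with open(path, "w") as fh:
        for si in truth.sweep_intervals:
            fh.write(f"{si.chrom}\t{si.start}\t{si.end}\t{','.join(si.targets)}\n")


def read_truth_bed(path: str | Path) -> list[SweepInterval]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        f = line.split("\t")
        out.append(SweepInterval(f[0], int(f[1]), int(f[2]), tuple(f[3].split(",")) if len(f) > 3 else ()))
    return out


def write_fasta(genomes: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genomes.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
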