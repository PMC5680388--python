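"""End-to-end pipeline: filter -> stats -> annotate -> structure -> scan -> enrich.

Each stage reads the previous stage's in-memory results, writes plain-text
outputs into the run directory and contributes row counts to a JSON manifest
(package version, parameters, input checksums, per-stage counts). A stage
failure aborts the run with a stage-named error. ``demo`` wires the whole
pipeline to a freshly simulated cohort with planted sweeps and reports how
well the scan recovers them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import enrich as enrich_mod
from . import popstruct, simcohort, sweepscan, varannot, varstats, vcfio
from .popmap import PopulationMap

log = logging.getLogger("sweepherd")

STAGES = ("filter", "stats", "annotate", "structure", "scan", "enrich")


@dataclass
class PipelineConfig:
    """Paths, stage toggles and per-stage parameters of one run."""

    vcf: str
    popmap: str
    outdir: str
    genes: str | None = None  # BED12
    fasta: str | None = None
    term_map: str | None = None
    known_sites: str | None = None
    chrom_lengths: dict[str, int] | None = None  # derived from fasta if absent
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    thresholds: vcfio.FilterThresholds = field(default_factory=vcfio.FilterThresholds)
    scan: sweepscan.ScanConfig = field(default_factory=sweepscan.ScanConfig)
    flank_bp: int = 1000
    splice_bp: int = 2
    ld_max_bp: int = 100_000
    ld_bin_bp: int = 10_000
    outgroup: str | None = None

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        for attr in ("vcf", "popmap"):
            if not Path(getattr(self, attr)).exists():
                raise FileNotFoundError(f"{attr} path {getattr(self, attr)!r} does not exist")
        if "annotate" in self.stages and (self.genes is None or self.fasta is None):
            raise ValueError("annotate stage requires gene models and a reference FASTA")
        if "enrich" in self.stages and ("scan" not in self.stages or self.term_map is None):
            raise ValueError("enrich stage requires the scan stage and a term map")
        if "scan" in self.stages and not (self.scan.target and self.scan.reference):
            raise ValueError("scan stage requires target and reference population sets")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "sweepherd",
        "parameters": {
            "thresholds": asdict(config.thresholds),
            "scan": asdict(config.scan),
            "flank_bp": config.flank_bp,
            "splice_bp": config.splice_bp,
        },
        "inputs": {
            name: _sha256(path)
            for name, path in (
                ("vcf", config.vcf), ("popmap", config.popmap), ("genes", config.genes),
                ("fasta", config.fasta), ("term_map", config.term_map),
            )
            if path
        },
        "stages": {},
    }

    popmap = PopulationMap.read_tsv(config.popmap)
    table = vcfio.read_vcf(config.vcf, popmap)
    chrom_lengths = config.chrom_lengths or _lengths_from_fasta(config.fasta)

    snps = indels = None
    gene_models: list[varannot.GeneModel] = []
    regions: list[sweepscan.CandidateRegion] = []

    for stage in STAGES:
        if stage not in config.stages:
            continue
        log.info("stage %s starting", stage)
        try:
            if stage == "filter":
                snps, indels = vcfio.split_snps_indels(table)
                snps = vcfio.filter_snps(snps, config.thresholds)
                indels = vcfio.filter_indels(indels, config.thresholds)
                vcfio.write_vcf(snps, out / "snps.filtered.vcf")
                vcfio.write_vcf(indels, out / "indels.filtered.vcf")
                vcfio.write_filter_report(snps, out / "filter_report_snps.tsv")
                vcfio.write_filter_report(indels, out / "filter_report_indels.tsv")
                manifest["stages"]["filter"] = {
                    "input_records": table.n_sites,
                    "snps_kept": snps.n_sites, "indels_kept": indels.n_sites,
                }
            elif stage == "stats":
                snps_t = snps if snps is not None else table
                total_bp = sum(chrom_lengths.values()) if chrom_lengths else None
                stats = {
                    "titv": varstats.titv_ratio(snps_t),
                    "het_hom_per_population": varstats.het_hom_ratio(snps_t, "population", popmap),
                    "depth_min_max_mean": varstats.site_depth_summary(snps_t),
                }
                if total_bp:
                    stats["pi_per_population"] = {
                        p: varstats.nucleotide_diversity(snps_t, p, total_bp, popmap)
                        for p in popmap.populations
                    }
                    varstats.snp_density_per_chromosome(snps_t, chrom_lengths).to_csv(
                        out / "snp_density.tsv", sep="\t", index=False)
                if indels is not None and indels.n_sites:
                    spectrum = varstats.indel_length_spectrum(indels)
                    with open(out / "indel_spectrum.tsv", "w") as fh:
                        fh.write("signed_length\tcount\n")
                        for k, v in spectrum.items():
                            fh.write(f"{k}\t{v}\n")
                if len(popmap.populations) >= 2:
                    sharing = varstats.population_sharing(snps_t, popmap)
                    stats["shared_by_all_fraction"] = sharing.shared_by_all_fraction
                    with open(out / "venn.tsv", "w") as fh:
                        fh.write("pattern\tcount\n")
                        for pattern, count in sorted(sharing.venn_cells.items()):
                            fh.write(f"{'|'.join(pattern) or '(none)'}\t{count}\n")
                if config.known_sites:
                    novel, known = varstats.novelty_vs_known(snps_t, config.known_sites)
                    stats["novel"], stats["known"] = novel, known
                with open(out / "stats.json", "w") as fh:
                    json.dump(stats, fh, indent=2, sort_keys=True, default=float)
                manifest["stages"]["stats"] = {"records": snps_t.n_sites}
            elif stage == "annotate":
                gene_models = varannot.read_bed12(config.genes)
                varannot.attach_cds_sequences(gene_models, config.fasta)
                results = []
                for t in (snps, indels):
                    if t is not None and t.n_sites:
                        results += varannot.annotate_table(
                            t, gene_models, flank=config.flank_bp, splice=config.splice_bp)
                varannot.write_annotation_tsv(results, out / "annotation.tsv")
                varannot.annotation_summary(results).to_csv(
                    out / "annotation_summary.tsv", sep="\t", index=False)
                manifest["stages"]["annotate"] = {"records": len(results)}
            elif stage == "structure":
                snps_t = snps if snps is not None else table
                thinned = popstruct.ld_thin(snps_t)
                dist = popstruct.pairwise_p_distance(thinned)
                (out / "nj.nwk").write_text(popstruct.nj_tree(dist, outgroup=config.outgroup) + "\n")
                vecs, vals = popstruct.pca(thinned, k=min(10, thinned.n_samples))
                with open(out / "pca.tsv", "w") as fh:
                    fh.write("sample\t" + "\t".join(f"PC{i+1}" for i in range(vecs.shape[1])) + "\n")
                    for s, row in zip(thinned.samples, vecs):
                        fh.write(s + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
                ld = popstruct.ld_r2(thinned, max_bp=config.ld_max_bp)
                popstruct.ld_decay(ld, config.ld_bin_bp).to_csv(out / "ld_decay.tsv", sep="\t", index=False)
                if len(popmap.populations) >= 2:
                    popstruct.pairwise_population_fst(snps_t, popmap).to_csv(out / "fst_pairwise.tsv", sep="\t")
                manifest["stages"]["structure"] = {
                    "thinned_snps": thinned.n_sites, "ld_pairs": len(ld.pairs),
                }
            elif stage == "scan":
                snps_t = snps if snps is not None else table
                stats_df, cuts, regions = sweepscan.run_scan(
                    snps_t, popmap, chrom_lengths, config.scan, gene_models or None)
                stats_df.to_csv(out / "windows.tsv", sep="\t", index=False, float_format="%.6g")
                with open(out / "regions.bed", "w") as fh:
                    for r in regions:
                        fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.n_windows}\t"
                                 f"{r.max_fst:.6g}\t{','.join(r.genes)}\n")
                afd = sweepscan.allele_frequency_difference(
                    snps_t, popmap, config.scan.target, config.scan.reference)
                afd.to_csv(out / "allele_freq_diff.tsv", sep="\t", index=False, float_format="%.6g")
                manifest["stages"]["scan"] = {
                    "windows": len(stats_df), "selected": int(stats_df["selected"].sum()),
                    "regions": len(regions), "fst_cut": cuts[0], "ratio_cut": cuts[1],
                    "candidate_genes": len({g for r in regions for g in r.genes}),
                }
            elif stage == "enrich":
                candidates = sorted({g for r in regions for g in r.genes})
                if candidates:
                    rows = enrich_mod.hypergeom_enrich(candidates, config.term_map)
                    enrich_mod.write_enrichment_tsv(rows, out / "enrichment.tsv")
                    n_sig = int(sum(bool(r.q <= 0.05) for r in rows))
                else:
                    (out / "enrichment.tsv").write_text("term_id\tterm_name\tk\tK\tn\tN\tp\tq\tmembers\n")
                    rows, n_sig = [], 0
                manifest["stages"]["enrich"] = {
                    "candidates": len(candidates), "terms_tested": len(rows), "significant": n_sig,
                }
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        log.info("stage %s done", stage)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _lengths_from_fasta(fasta: str | None) -> dict[str, int] | None:
    if fasta is None:
        return None
    from Bio import SeqIO

    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}


# ---------------------------------------------------------------------------
# demo: simulate + full pipeline + sweep-recovery summary


def demo_sim_config(seed: int) -> simcohort.SimConfig:
    """The standard benchmark cohort: 2 pops x 20 diploids, 10 Mb, 2 sweeps.

    Sweeps target pop1 and together cover 3% of the genome, keeping the
    planted signal inside the scan's default 5% empirical tail.
    """
    return simcohort.SimConfig(
        n_populations=2, samples_per_pop=20,
        chrom_lengths={"chr1": 5_000_000, "chr2": 5_000_000},
        mu_density=0.002, fst_bg=0.05,
        sweep_intervals=[
            simcohort.SweepInterval("chr1", 2_000_000, 2_150_000, ("pop1",)),
            simcohort.SweepInterval("chr2", 3_200_000, 3_350_000, ("pop1",)),
        ],
        sweep_pi_reduction=8.0, sweep_freq_shift=0.7,
        indel_fraction=0.1, missing_rate=0.02, maf_floor=0.05, seed=seed,
    )


def sweep_recovery(regions, truth_intervals, chrom_lengths) -> tuple[float, float]:
    """(fraction of sweep bp inside regions, fraction of non-sweep bp flagged)."""
    sweep_bp = sum(si.end - si.start for si in truth_intervals)
    genome_bp = sum(chrom_lengths.values())
    hit = 0
    region_bp = 0
    for r in regions:
        region_bp += r.end - r.start
        for si in truth_intervals:
            if si.chrom == r.chrom:
                hit += max(0, min(si.end, r.end) - max(si.start, r.start))
    recovered = hit / sweep_bp if sweep_bp else float("nan")
    fp = (region_bp - hit) / (genome_bp - sweep_bp) if genome_bp > sweep_bp else float("nan")
    return recovered, fp


def demo(seed: int = 0, outdir: str | Path = "demo_out") -> dict:
    """Simulate the benchmark cohort, run every stage, report sweep recovery."""
    out = Path(outdir)
    (out / "input").mkdir(parents=True, exist_ok=True)
    cfg = demo_sim_config(seed)
    table, popmap, truth = simcohort.simulate_cohort(cfg)
    models, genomes = simcohort.simulate_gene_models(cfg, genes_per_chrom=40)
    simcohort.harmonize_with_reference(table, genomes, seed=seed)

    vcf_path = out / "input" / "cohort.vcf"
    vcfio.write_vcf(table, vcf_path)
    popmap.write_tsv(out / "input" / "popmap.tsv")
    simcohort.write_truth(truth, out / "input" / "truth.bed")
    varannot.write_bed12(models, out / "input" / "genes.bed12")
    simcohort.write_fasta(genomes, out / "input" / "ref.fa")
    _write_demo_term_map(models, out / "input" / "terms.tsv", seed)

    pipe_cfg = PipelineConfig(
        vcf=str(vcf_path), popmap=str(out / "input" / "popmap.tsv"),
        outdir=str(out / "run"),
        genes=str(out / "input" / "genes.bed12"), fasta=str(out / "input" / "ref.fa"),
        term_map=str(out / "input" / "terms.tsv"),
        chrom_lengths=dict(cfg.chrom_lengths),
        scan=sweepscan.ScanConfig(target=["pop1"], reference=["pop2"], direction="depleted"),
    )
    manifest = run_pipeline(pipe_cfg)

    regions = [
        sweepscan.CandidateRegion(f[0], int(f[1]), int(f[2]), int(f[3]), float(f[4]), 0.0)
        for f in (line.split("\t") for line in (out / "run" / "regions.bed").read_text().splitlines())
    ]
    recovered, fp = sweep_recovery(regions, truth.sweep_intervals, cfg.chrom_lengths)
    summary = {
        "seed": seed,
        "sweep_bp_recovered_fraction": recovered,
        "non_sweep_bp_flagged_fraction": fp,
        "n_regions": len(regions),
        "realized_pi_ratio": truth.realized_pi_ratio,
    }
    with open(out / "recovery.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    manifest["recovery"] = summary
    return manifest


def _write_demo_term_map(models, path, seed: int) -> None:
    """Synthetic gene -> term map: each gene gets 1-3 of 8 generic terms."""
    rng = np.random.default_rng([seed, 4242])
    terms = [(f"T{i:04d}", f"process_{i}") for i in range(8)]
    with open(path, "w") as fh:
        for m in models:
            for t in rng.choice(len(terms), size=int(rng.integers(1, 4)), replace=False):
                fh.write(f"{m.gene_id}\t{terms[t][0]}\t{terms[t][1]}\n")
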