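"""Variant annotation against transcript models.

Classifies each variant by genomic location (exonic, splicing, UTR, intronic,
up/downstream, intergenic, ncRNA_*) with a fixed precedence, and classifies
exonic coding variants by protein effect (synonymous/nonsynonymous SNV,
stopgain, stoploss; frameshift vs non-frameshift for indels), strand-aware
with the standard genetic code. The category system mirrors the default
scheme of the Annovar-style gene annotation used for resequencing summaries.

Coordinates: VCF input is 1-based; all internal arithmetic is 0-based
half-open; reported output is 1-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq

LOCATION_PRECEDENCE = {
    "exonic": 0, "ncRNA_exonic": 0,
    "splicing": 1,
    "UTR5": 2, "UTR3": 2, "UTR5;UTR3": 2,
    "intronic": 3, "ncRNA_intronic": 3,
    "upstream": 4, "downstream": 4, "upstream/downstream": 4,
    "intergenic": 5,
}

COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """One transcript: exon structure, CDS span and spliced CDS sequence.

    ``exons`` are 0-based half-open genomic intervals, sorted, non-overlapping.
    ``cds_start``/``cds_end`` bound the genomic CDS region (equal for ncRNA).
    ``cds_seq`` is the spliced CDS, 5'->3' in coding orientation.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    cds_seq: str | None = None

    def __post_init__(self):
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if self.coding and self.cds_seq is not None and len(self.cds_seq) % 3 != 0:
            raise ValueError(f"CDS length of {self.transcript_id} not a multiple of 3")

    @property
    def coding(self) -> bool:
        return self.cds_end > self.cds_start

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    def cds_exon_intervals(self) -> list[tuple[int, int]]:
        out = []
        for s, e in self.exons:
            cs, ce = max(s, self.cds_start), min(e, self.cds_end)
            if ce > cs:
                out.append((cs, ce))
        return out

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_exon_intervals())

    def cds_index_of(self, gpos0: int) -> int | None:
        """Spliced CDS index (coding orientation) of a genomic position, or None."""
        offset = 0
        plus_index = None
        for cs, ce in self.cds_exon_intervals():
            if cs <= gpos0 < ce:
                plus_index = offset + (gpos0 - cs)
            offset += ce - cs
        if plus_index is None:
            return None
        return plus_index if self.strand == "+" else offset - 1 - plus_index


@dataclass
class AnnotationResult:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    location: str
    effect: str  # "n/a" unless exonic coding
    genes: list[str] = field(default_factory=list)
    detail: list[str] = field(default_factory=list)  # per-transcript calls


# ---------------------------------------------------------------------------
# location classification


def classify_location(variant, gene_models: list[GeneModel],
                      flank: int = 1000, splice: int = 2) -> tuple[str, list[str]]:
    """Locate a variant relative to transcript models.

    Precedence: exonic > splicing > UTR > intronic > up/downstream >
    intergenic. A variant in the UTR5 of one transcript and the UTR3 of
    another reports "UTR5;UTR3"; analogously "upstream/downstream".
    ncRNA transcripts yield ncRNA_exonic / ncRNA_intronic.
    """
    p = int(variant.pos) - 1
    chrom = variant.chrom
    models = [m for m in gene_models if m.chrom == chrom]
    if not models and not any(m.chrom == chrom for m in gene_models):
        if gene_models:
            warnings.warn(f"chromosome {chrom!r} absent from gene models; classifying as intergenic")
    calls: list[tuple[int, str, str]] = []  # (rank, category, gene)
    for m in models:
        cat = _locate_in_transcript(p, m, flank, splice)
        if cat is not None:
            calls.append((LOCATION_PRECEDENCE[cat], cat, m.gene_id))
    if not calls:
        return "intergenic", []
    best = min(rank for rank, _, _ in calls)
    cats = {c for rank, c, _ in calls if rank == best}
    genes = sorted({g for rank, _, g in calls if rank == best})
    if best == 2 and {"UTR5", "UTR3"} <= cats:
        return "UTR5;UTR3", genes
    if best == 4 and {"upstream", "downstream"} <= cats:
        return "upstream/downstream", genes
    # deterministic pick among same-rank labels (e.g. exonic vs ncRNA_exonic)
    return sorted(cats)[0], genes


def _locate_in_transcript(p: int, m: GeneModel, flank: int, splice: int) -> str | None:
    if m.tx_start <= p < m.tx_end:
        in_exon = any(s <= p < e for s, e in m.exons)
        if not m.coding:
            return "ncRNA_exonic" if in_exon else "ncRNA_intronic"
        if in_exon:
            if m.cds_start <= p < m.cds_end:
                return "exonic"
            if p < m.cds_start:
                return "UTR5" if m.strand == "+" else "UTR3"
            return "UTR3" if m.strand == "+" else "UTR5"
        # intron: distance (in bp) from the nearest exon boundary
        for (s1, e1), (s2, e2) in zip(m.exons, m.exons[1:]):
            if e1 <= p < s2:
                dist = min(p - e1 + 1, s2 - p)
                return "splicing" if dist <= splice else "intronic"
        return "intronic"  # unreachable for well-formed models
    if m.strand == "+":
        if m.tx_start - flank <= p < m.tx_start:
            return "upstream"
        if m.tx_end <= p < m.tx_end + flank:
            return "downstream"
    else:
        if m.tx_end <= p < m.tx_end + flank:
            return "upstream"
        if m.tx_start - flank <= p < m.tx_start:
            return "downstream"
    return None


# ---------------------------------------------------------------------------
# coding-effect classification


def classify_coding_effect(snp, gene_model: GeneModel) -> str:
    """Protein effect of an exonic coding SNP on one transcript.

    Returns one of synonymous SNV / nonsynonymous SNV / stopgain / stoploss /
    unknown. "unknown" flags an incomplete CDS or a CDS sequence that
    disagrees with the variant's REF allele.
    """
    if gene_model.cds_seq is None:
        return "unknown"
    p = int(snp.pos) - 1
    idx = gene_model.cds_index_of(p)
    if idx is None:
        return "unknown"
    cds = gene_model.cds_seq.upper()
    if len(cds) % 3 != 0 or idx >= len(cds):
        return "unknown"
    ref_base, alt_base = snp.ref.upper(), snp.alt.upper()
    if gene_model.strand == "-":
        ref_base, alt_base = revcomp(ref_base), revcomp(alt_base)
    if cds[idx] != ref_base:
        warnings.warn(
            f"CDS of {gene_model.transcript_id} disagrees with REF at {snp.chrom}:{snp.pos}"
        )
        return "unknown"
    codon_i = idx // 3
    ref_codon = cds[3 * codon_i: 3 * codon_i + 3]
    within = idx % 3
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa != "*" and alt_aa == "*":
        return "stopgain"
    if ref_aa == "*" and alt_aa != "*":
        return "stoploss"
    return "synonymous SNV" if ref_aa == alt_aa else "nonsynonymous SNV"


def classify_indel_effect(indel, gene_model: GeneModel) -> str:
    """frameshift / non-frameshift for a CDS-overlapping indel, else n/a."""
    if not gene_model.coding:
        return "n/a"
    pos0 = int(indel.pos) - 1
    ref_len, alt_len = len(indel.ref), len(indel.alt)
    if ref_len > alt_len:  # deletion: bases after the anchor are removed
        affected = (pos0 + 1, pos0 + ref_len)
        overlaps = any(max(s, affected[0]) < min(e, affected[1])
                       for s, e in gene_model.cds_exon_intervals())
    else:  # insertion: anchored at pos0
        overlaps = any(s <= pos0 < e for s, e in gene_model.cds_exon_intervals())
    if not overlaps:
        return "n/a"
    return "frameshift" if abs(ref_len - alt_len) % 3 != 0 else "non-frameshift"


def annotate_table(table, gene_models: list[GeneModel],
                   flank: int = 1000, splice: int = 2) -> list[AnnotationResult]:
    """Annotate every record of a variant table (location + effect)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in gene_models:
        by_chrom.setdefault(m.chrom, []).append(m)
    results = []
    for rec in table.records():
        models = by_chrom.get(rec.chrom, [])
        location, genes = classify_location(rec, models, flank=flank, splice=splice)
        effect = "n/a"
        detail = []
        if location == "exonic":
            gene_set = set(genes)
            for m in models:
                if m.gene_id not in gene_set or not m.coding:
                    continue
                if rec.is_snp:
                    call = classify_coding_effect(rec, m)
                else:
                    call = classify_indel_effect(rec, m)
                detail.append(f"{m.transcript_id}:{call}")
                if effect == "n/a" and call != "n/a":
                    effect = call
        results.append(AnnotationResult(
            chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=rec.alt,
            location=location, effect=effect, genes=genes, detail=detail,
        ))
    return results


def annotation_summary(results: list[AnnotationResult]):
    """Category counts and percentages plus affected-gene counts per effect."""
    import pandas as pd

    total = len(results)
    loc_counts: dict[str, int] = {}
    eff_counts: dict[str, int] = {}
    eff_genes: dict[str, set[str]] = {}
    for r in results:
        loc_counts[r.location] = loc_counts.get(r.location, 0) + 1
        if r.effect != "n/a":
            eff_counts[r.effect] = eff_counts.get(r.effect, 0) + 1
            eff_genes.setdefault(r.effect, set()).update(r.genes)
    rows = [
        {"kind": "location", "category": k, "count": v,
         "percent": 100.0 * v / total if total else 0.0, "genes": ""}
        for k, v in sorted(loc_counts.items())
    ] + [
        {"kind": "effect", "category": k, "count": v,
         "percent": 100.0 * v / total if total else 0.0,
         "genes": len(eff_genes.get(k, ()))}
        for k, v in sorted(eff_counts.items())
    ]
    return pd.DataFrame(rows, columns=["kind", "category", "count", "percent", "genes"])


# ---------------------------------------------------------------------------
# model I/O (BED12 + FASTA)


def write_bed12(models: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            sizes = ",".join(str(e - s) for s, e in m.exons) + ","
            starts = ",".join(str(s - m.tx_start) for s, _ in m.exons) + ","
            fh.write("\t".join(map(str, [
                m.chrom, m.tx_start, m.tx_end, f"{m.gene_id}|{m.transcript_id}", 0,
                m.strand, m.cds_start, m.cds_end, "0,0,0", len(m.exons), sizes, starts,
            ])) + "\n")


def read_bed12(path: str | Path) -> list[GeneModel]:
    models = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.rstrip("\n").split("\t")
        chrom, start = f[0], int(f[1])
        name = f[3]
        gene_id, _, tx_id = name.partition("|")
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        starts = [int(x) for x in f[11].rstrip(",").split(",")]
        exons = [(start + s, start + s + sz) for s, sz in zip(starts, sizes)]
        models.append(GeneModel(
            gene_id=gene_id, transcript_id=tx_id or gene_id, chrom=chrom,
            strand=f[5], exons=exons, cds_start=int(f[6]), cds_end=int(f[7]),
        ))
    return models


def attach_cds_sequences(models: list[GeneModel], fasta_path: str | Path) -> None:
    """Fill ``cds_seq`` of coding models from a reference FASTA, in place."""
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    for m in models:
        if not m.coding:
            continue
        genome = seqs[m.chrom]
        spliced = "".join(genome[s:e] for s, e in m.cds_exon_intervals())
        m.cds_seq = spliced if m.strand == "+" else revcomp(spliced)


def write_annotation_tsv(results: list[AnnotationResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tlocation\teffect\tgenes\tdetail\n")
        for r in results:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t{r.location}\t{r.effect}\t"
                     f"{','.join(r.genes)}\t{','.join(r.detail)}\n")
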