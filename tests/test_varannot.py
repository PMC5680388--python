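"""Location and coding-effect classification against transcript models."""

from dataclasses import dataclass

import numpy as np
import pytest
from Bio.Seq import Seq

from sweepherd.simcohort import SimConfig, simulate_gene_models
from sweepherd.varannot import (
    GeneModel,
    annotation_summary,
    annotate_table,
    classify_coding_effect,
    classify_indel_effect,
    classify_location,
    read_bed12,
    revcomp,
    write_bed12,
)

from conftest import make_table


@dataclass
class V:
    chrom: str
    pos: int  # 1-based
    ref: str = "A"
    alt: str = "G"

    @property
    def is_snp(self):
        return len(self.ref) == 1 and len(self.alt) == 1


@pytest.fixture
def plus_model():
    """+ strand, 2 exons: [1000,1100) and [1200,1320); CDS [1050,1260)."""
    cds_exonic = 50 + 60  # 50 bp in exon 1, 60 bp in exon 2 -> 110? keep 3-divisible
    # choose CDS [1050, 1100) + [1200, 1261) = 50 + 61: adjust to 111 (multiple of 3)
    return GeneModel(
        gene_id="G1", transcript_id="T1", chrom="chr1", strand="+",
        exons=[(1000, 1100), (1200, 1320)], cds_start=1050, cds_end=1261,
    )


class TestLocation:
    def test_exonic_cds_containment(self, plus_model):
        assert classify_location(V("chr1", 1061), [plus_model]) == ("exonic", ["G1"])

    def test_utr5_and_utr3(self, plus_model):
        assert classify_location(V("chr1", 1010), [plus_model])[0] == "UTR5"
        assert classify_location(V("chr1", 1300), [plus_model])[0] == "UTR3"

    def test_upstream_within_flank(self, plus_model):
        # 500 bp 5' of the TSS on the + strand
        assert classify_location(V("chr1", 501), [plus_model])[0] == "upstream"
        assert classify_location(V("chr1", 1330), [plus_model])[0] == "downstream"
        assert classify_location(V("chr1", 2500), [plus_model])[0] == "intergenic"

    @pytest.mark.parametrize("pos0, expected", [
        (1100, "splicing"),  # 1 bp into the intron from the donor side
        (1101, "splicing"),  # 2 bp in
        (1102, "intronic"),  # 3 bp in, outside the 2 bp window
        (1199, "splicing"),  # 1 bp from the acceptor side
        (1197, "intronic"),
    ])
    def test_splice_window_boundary(self, plus_model, pos0, expected):
        assert classify_location(V("chr1", pos0 + 1), [plus_model])[0] == expected

    def test_minus_strand_flanks_are_strand_aware(self):
        m = GeneModel("G2", "T2", "chr1", "-", [(5000, 5300)], 5060, 5240)
        assert classify_location(V("chr1", 5400), [m])[0] == "upstream"
        assert classify_location(V("chr1", 4950), [m])[0] == "downstream"
        assert classify_location(V("chr1", 5010), [m])[0] == "UTR3"
        assert classify_location(V("chr1", 5290), [m])[0] == "UTR5"

    def test_ncrna_categories(self):
        m = GeneModel("N1", "TN1", "chr1", "+", [(100, 200), (300, 400)], 100, 100)
        assert classify_location(V("chr1", 150), [m])[0] == "ncRNA_exonic"
        assert classify_location(V("chr1", 251), [m])[0] == "ncRNA_intronic"

    def test_between_two_genes_upstream_downstream(self):
        left = GeneModel("GL", "TL", "chr1", "+", [(0, 1000)], 0, 300)
        right = GeneModel("GR", "TR", "chr1", "+", [(1500, 2500)], 1800, 2100)
        cat, genes = classify_location(V("chr1", 1201), [left, right])
        assert cat == "upstream/downstream" and genes == ["GL", "GR"]

    def test_chrom_absent_from_models_warns_intergenic(self, plus_model):
        with pytest.warns(UserWarning, match="absent"):
            cat, _ = classify_location(V("chrZ", 100), [plus_model])
        assert cat == "intergenic"

    def test_precedence_exonic_over_flank(self, plus_model):
        other = GeneModel("G3", "T3", "chr1", "+", [(1400, 2000)], 1500, 1800)
        # position exonic in plus_model, upstream of other: exonic wins
        assert classify_location(V("chr1", 1061), [plus_model, other])[0] == "exonic"


class TestCodingEffect:
    def _model(self, cds, strand="+"):
        """Single-exon model: CDS occupies [100, 100+len) on + orientation."""
        seq = cds if strand == "+" else revcomp(cds)
        return GeneModel("G", "T", "chr1", strand, [(100, 100 + len(cds))],
                         100, 100 + len(cds), cds_seq=cds), seq

    def test_stopgain_tgg_to_tag(self):
        cds = "ATG" + "TGG" + "TAA"
        m, _ = self._model(cds)
        # TGG codon occupies 0-based 103..105; position 2 of the codon is 104
        assert classify_coding_effect(V("chr1", 105, "G", "A"), m) == "stopgain"

    def test_synonymous_gga_to_ggg(self):
        cds = "ATG" + "GGA" + "TAA"
        m, _ = self._model(cds)
        assert classify_coding_effect(V("chr1", 106, "A", "G"), m) == "synonymous SNV"

    def test_stoploss_taa_to_caa(self):
        cds = "ATG" + "AAA" + "TAA"
        m, _ = self._model(cds)
        assert classify_coding_effect(V("chr1", 107, "T", "C"), m) == "stoploss"

    def test_nonsynonymous(self):
        cds = "ATG" + "AAA" + "TAA"  # AAA (Lys) -> AGA (Arg)
        m, _ = self._model(cds)
        assert classify_coding_effect(V("chr1", 105, "A", "G"), m) == "nonsynonymous SNV"

    def test_minus_strand_alleles_are_complemented(self):
        cds = "ATG" + "TGG" + "TAA"
        m, _ = self._model(cds, strand="-")
        # genomic layout is revcomp(cds): transcript index 4 (the G of TGG at
        # codon position 2) sits at genomic 0-based 100 + (9-1-4) = 104;
        # genomic C->T corresponds to transcript G->A (TGG -> TAG)
        assert classify_coding_effect(V("chr1", 105, "C", "T"), m) == "stopgain"

    def test_ref_mismatch_is_unknown(self):
        cds = "ATG" + "AAA" + "TAA"
        m, _ = self._model(cds)
        with pytest.warns(UserWarning, match="disagrees"):
            assert classify_coding_effect(V("chr1", 105, "C", "G"), m) == "unknown"


class TestIndelEffect:
    def test_frameshift_and_inframe(self):
        m = GeneModel("G", "T", "chr1", "+", [(100, 400)], 100, 400)
        assert classify_indel_effect(V("chr1", 150, "ATT", "A"), m) == "frameshift"
        assert classify_indel_effect(V("chr1", 150, "A", "ATTT"), m) == "non-frameshift"

    def test_non_cds_indel_is_na(self):
        m = GeneModel("G", "T", "chr1", "+", [(100, 200), (300, 400)], 100, 400)
        assert classify_indel_effect(V("chr1", 251, "ATT", "A"), m) == "n/a"


def test_annotation_summary_counts():
    models = [GeneModel("G1", "T1", "chr1", "+", [(1000, 1300)], 1000, 1300,
                        cds_seq=None)]
    t = make_table([
        {"pos": 1100, "genotypes": [1]},
        {"pos": 1200, "genotypes": [1]},
        {"pos": 500, "genotypes": [1]},
        {"pos": 5000, "genotypes": [1]},
    ], ["s"])
    res = annotate_table(t, models)
    full = annotation_summary(res)
    df = full[full["kind"] == "location"].set_index("category")
    assert df.loc["exonic", "count"] == 2
    assert df.loc["upstream", "count"] == 1
    assert df.loc["intergenic", "count"] == 1
    assert df["count"].sum() == 4
    assert annotation_summary([]).empty


# ---------------------------------------------------------------------------
# simulated gene models


def test_simulated_models_translate_cleanly_and_deterministically():
    cfg = SimConfig(chrom_lengths={"chr1": 200_000}, seed=5)
    models, genomes = simulate_gene_models(cfg, genes_per_chrom=6, noncoding_fraction=0.2)
    models2, genomes2 = simulate_gene_models(cfg, genes_per_chrom=6, noncoding_fraction=0.2)
    assert genomes == genomes2
    assert [m.exons for m in models] == [m.exons for m in models2]
    seen_minus = False
    for m in models:
        if not m.coding:
            continue
        genome = genomes[m.chrom]
        spliced = "".join(genome[s:e] for s, e in m.cds_exon_intervals())
        if m.strand == "-":
            spliced = revcomp(spliced)
            seen_minus = True
        assert spliced == m.cds_seq
        aa = str(Seq(spliced).translate())
        assert aa.startswith("M") and aa.endswith("*") and "*" not in aa[:-1]
    assert seen_minus or any(m.strand == "-" for m in models)


def test_bed12_roundtrip():
    cfg = SimConfig(chrom_lengths={"chr1": 200_000}, seed=2)
    models, _ = simulate_gene_models(cfg, genes_per_chrom=4)
    import io, tempfile, os
    from pathlib import Path
    with tempfile.TemporaryDirectory() as d:
        p = Path(d) / "m.bed12"
        write_bed12(models, p)
        back = read_bed12(p)
    assert [(m.chrom, m.strand, m.exons, m.cds_start, m.cds_end) for m in models] == \
           [(m.chrom, m.strand, m.exons, m.cds_start, m.cds_end) for m in back]


def place_truth_variants(models, genomes, rng):
    """Programmatically place variants with independently derived truth.

    The expected effect comes from full re-translation of the mutated
    spliced CDS (a different route than the codon-local classifier).
    """
    cases = []  # (variant, model, expected_effect)
    for m in models:
        if not m.coding:
            continue
        genome = genomes[m.chrom]
        cds_positions = [p for s, e in m.cds_exon_intervals() for p in range(s, e)]
        for p0 in rng.choice(cds_positions, size=min(20, len(cds_positions)), replace=False):
            ref = genome[p0]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            # oracle: mutate the genome, re-splice, re-translate
            mut = genome[:p0] + alt + genome[p0 + 1:]
            spliced_ref = "".join(genome[s:e] for s, e in m.cds_exon_intervals())
            spliced_alt = "".join(mut[s:e] for s, e in m.cds_exon_intervals())
            if m.strand == "-":
                spliced_ref, spliced_alt = revcomp(spliced_ref), revcomp(spliced_alt)
            aa_ref = str(Seq(spliced_ref).translate())
            aa_alt = str(Seq(spliced_alt).translate())
            diff = [(a, b) for a, b in zip(aa_ref, aa_alt) if a != b]
            if not diff:
                expected = "synonymous SNV"
            elif diff[0][1] == "*":
                expected = "stopgain"
            elif diff[0][0] == "*":
                expected = "stoploss"
            else:
                expected = "nonsynonymous SNV"
            cases.append((V(m.chrom, p0 + 1, ref, alt), m, expected))
    return cases


def test_truth_class_accuracy_on_simulated_models():
    """Classifier agrees with full re-translation on every placed variant."""
    cfg = SimConfig(chrom_lengths={"chr1": 300_000}, seed=9)
    models, genomes = simulate_gene_models(cfg, genes_per_chrom=8, noncoding_fraction=0.0)
    rng = np.random.default_rng(3)
    cases = place_truth_variants(models, genomes, rng)
    assert len(cases) >= 100
    for v, m, expected in cases:
        assert classify_coding_effect(v, m) == expected, (v, m.transcript_id)


def test_effect_calls_are_strand_symmetric():
    """Reverse-complementing genome and models leaves every call unchanged."""
    cfg = SimConfig(chrom_lengths={"chr1": 120_000}, seed=13)
    models, genomes = simulate_gene_models(cfg, genes_per_chrom=3, noncoding_fraction=0.0)
    L = len(genomes["chr1"])
    rc_genome = revcomp(genomes["chr1"])
    rng = np.random.default_rng(8)
    for m in models:
        rc_model = GeneModel(
            m.gene_id, m.transcript_id, m.chrom,
            "-" if m.strand == "+" else "+",
            [(L - e, L - s) for s, e in m.exons],
            L - m.cds_end, L - m.cds_start, cds_seq=m.cds_seq,
        )
        genome = genomes["chr1"]
        cds_positions = [p for s, e in m.cds_exon_intervals() for p in range(s, e)]
        for p0 in rng.choice(cds_positions, size=10, replace=False):
            ref = genome[p0]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            fwd = classify_coding_effect(V("chr1", p0 + 1, ref, alt), m)
            rc_p0 = L - 1 - p0
            rc = classify_coding_effect(
                V("chr1", rc_p0 + 1, revcomp(ref), revcomp(alt)), rc_model)
            assert fwd == rc
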