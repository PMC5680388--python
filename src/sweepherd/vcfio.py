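"""Variant table container, VCF parsing/writing and hard filtration.

The filtration reproduces a GATK-style hard-filter protocol for a jointly
called goat resequencing cohort: SNPs and indels are split, each class is
screened by site-quality annotations (QD, ReadPosRankSum, FS, QUAL), and the
survivors are screened by cohort-level call rate and minor-allele frequency.
Thresholds live in :class:`FilterThresholds`; every removal is attributed to
the first failing rule so that survivor + per-rule counts always reconcile
with the input count.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .popmap import PopulationMap

MISSING = -1  # genotype dosage sentinel

# attribution order follows the order the rules are conventionally quoted in
SNP_RULES = ("qd", "rprs", "fs", "qual", "missing", "maf")
INDEL_RULES = ("qual20", "qd", "rprs", "fs", "qual", "size", "maf")


@dataclass(frozen=True)
class FilterThresholds:
    """Hard-filter cutoffs for the joint call set.

    ``qual_min_snp`` / ``qual_min_indel_b`` are the cohort-calibrated QUAL
    cutoffs; ``qual_min_indel_a`` is the generic low-quality floor that the
    indel protocol applies in addition.  ``max_missing`` is the VCFtools
    convention: the minimum fraction of called genotypes required to keep a
    site.  ``max_indel_size`` is inclusive (a 25 bp indel is kept).
    """

    qd_min: float = 2.0
    rprs_min: float = -8.0
    fs_max: float = 10.0
    qual_min_snp: float = 1349.1
    qual_min_indel_a: float = 20.0
    qual_min_indel_b: float = 1257.74
    max_missing: float = 0.7
    maf_min: float = 0.05
    max_indel_size: int = 25

    def __post_init__(self):
        if not 0.0 <= self.max_missing <= 1.0:
            raise ValueError("max_missing must be in [0, 1]")


@dataclass
class VariantRecord:
    """One biallelic site; a row view of :class:`VariantTable`."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float
    qd: float
    fs: float
    rprs: float  # NaN when the annotation is absent
    site_dp: float
    genotypes: np.ndarray  # per-sample alt dosage, -1 = missing

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def indel_size(self) -> int:
        return abs(len(self.ref) - len(self.alt))


class VariantTable:
    """Columnar store of biallelic variant records.

    Rows are sorted by (chrom, pos); sample order is fixed across rows.
    ``genotypes`` holds per-sample alt-allele dosages (0/1/2, -1 missing) as
    an ``(n_sites, n_samples)`` int8 array.  ``provenance`` accumulates one
    entry per applied filter with per-rule removal counts.
    """

    def __init__(
        self,
        chrom: np.ndarray,
        pos: np.ndarray,
        ref: np.ndarray,
        alt: np.ndarray,
        qual: np.ndarray,
        qd: np.ndarray,
        fs: np.ndarray,
        rprs: np.ndarray,
        site_dp: np.ndarray,
        genotypes: np.ndarray,
        samples: list[str],
        sample_dp: np.ndarray | None = None,
        provenance: list[dict] | None = None,
    ):
        n = len(pos)
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(ref, dtype=object)
        self.alt = np.asarray(alt, dtype=object)
        self.qual = np.asarray(qual, dtype=np.float64)
        self.qd = np.asarray(qd, dtype=np.float64)
        self.fs = np.asarray(fs, dtype=np.float64)
        self.rprs = np.asarray(rprs, dtype=np.float64)
        self.site_dp = np.asarray(site_dp, dtype=np.float64)
        self.genotypes = np.asarray(genotypes, dtype=np.int8).reshape(n, len(samples))
        self.samples = list(samples)
        self.sample_dp = None if sample_dp is None else np.asarray(sample_dp, dtype=np.int32)
        self.provenance: list[dict] = list(provenance or [])
        for arr in (self.chrom, self.ref, self.alt, self.qual, self.qd, self.fs, self.rprs, self.site_dp):
            if len(arr) != n:
                raise ValueError("column length mismatch")

    # -- basic protocol ----------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def __len__(self) -> int:
        return self.n_sites

    @property
    def is_snp(self) -> np.ndarray:
        reflen = np.fromiter((len(r) for r in self.ref), dtype=np.int64, count=self.n_sites)
        altlen = np.fromiter((len(a) for a in self.alt), dtype=np.int64, count=self.n_sites)
        return (reflen == 1) & (altlen == 1)

    @property
    def indel_size(self) -> np.ndarray:
        """|len(ref) - len(alt)| per site (0 for SNPs)."""
        reflen = np.fromiter((len(r) for r in self.ref), dtype=np.int64, count=self.n_sites)
        altlen = np.fromiter((len(a) for a in self.alt), dtype=np.int64, count=self.n_sites)
        return np.abs(reflen - altlen)

    def record(self, i: int) -> VariantRecord:
        return VariantRecord(
            chrom=self.chrom[i], pos=int(self.pos[i]), ref=self.ref[i], alt=self.alt[i],
            qual=float(self.qual[i]), qd=float(self.qd[i]), fs=float(self.fs[i]),
            rprs=float(self.rprs[i]), site_dp=float(self.site_dp[i]),
            genotypes=self.genotypes[i],
        )

    def records(self):
        for i in range(self.n_sites):
            yield self.record(i)

    def subset(self, mask_or_idx, provenance_entry: dict | None = None) -> "VariantTable":
        idx = np.asarray(mask_or_idx)
        prov = self.provenance + ([provenance_entry] if provenance_entry else [])
        return VariantTable(
            self.chrom[idx], self.pos[idx], self.ref[idx], self.alt[idx],
            self.qual[idx], self.qd[idx], self.fs[idx], self.rprs[idx],
            self.site_dp[idx], self.genotypes[idx], self.samples,
            sample_dp=None if self.sample_dp is None else self.sample_dp[idx],
            provenance=prov,
        )

    # -- cohort-level site statistics --------------------------------------
    def call_rate(self) -> np.ndarray:
        return (self.genotypes != MISSING).sum(axis=1) / self.n_samples

    def alt_freq(self, sample_idx: list[int] | np.ndarray | None = None) -> np.ndarray:
        """Alt-allele frequency over called genotypes (NaN if none called)."""
        g = self.genotypes if sample_idx is None else self.genotypes[:, sample_idx]
        called = g != MISSING
        n_chrom = 2 * called.sum(axis=1)
        alt = np.where(called, g, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_chrom > 0, alt / np.maximum(n_chrom, 1), np.nan)

    def maf(self) -> np.ndarray:
        af = self.alt_freq()
        return np.minimum(af, 1.0 - af)


# ---------------------------------------------------------------------------
# parsing


def read_vcf(path: str | Path, population_map: PopulationMap | None = None) -> VariantTable:
    """Parse a VCF into a :class:`VariantTable`.

    Only biallelic records are kept; multi-allelic records are skipped and
    counted in the table's provenance. Missing INFO annotations become NaN.
    If a population map is given, every VCF sample must appear in it.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if population_map is not None:
        unknown = [s for s in samples if s not in population_map]
        if unknown:
            raise ValueError(f"samples absent from population map: {unknown}")

    cols: dict[str, list] = {k: [] for k in ("chrom", "pos", "ref", "alt", "qual", "qd", "fs", "rprs", "dp")}
    gts: list[np.ndarray] = []
    dps: list[np.ndarray] = []
    have_fmt_dp = "DP" in [f["ID"] for f in _format_headers(vcf)]
    n_multi = 0
    last = None
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        key = (v.CHROM, v.POS)
        if last is not None and last[0] == v.CHROM and v.POS < last[1]:
            raise ValueError(f"VCF not position-sorted at {v.CHROM}:{v.POS}")
        last = key
        cols["chrom"].append(v.CHROM)
        cols["pos"].append(v.POS)
        cols["ref"].append(v.REF)
        cols["alt"].append(v.ALT[0])
        cols["qual"].append(np.nan if v.QUAL is None else v.QUAL)
        cols["qd"].append(_info_float(v, "QD"))
        cols["fs"].append(_info_float(v, "FS"))
        cols["rprs"].append(_info_float(v, "ReadPosRankSum"))
        cols["dp"].append(_info_float(v, "DP"))
        # gts012: 0/1/2 = dosage, 3 = unknown
        g = np.asarray(v.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        gts.append(g)
        if have_fmt_dp:
            d = v.format("DP")
            dps.append(np.full(len(samples), -1, dtype=np.int32) if d is None
                       else np.where(d[:, 0] < 0, -1, d[:, 0]).astype(np.int32))
    vcf.close()

    n = len(cols["pos"])
    prov = [{"stage": "read_vcf", "path": Path(path).name, "records": n, "multiallelic_skipped": n_multi}]
    return VariantTable(
        np.array(cols["chrom"], dtype=object), np.array(cols["pos"], dtype=np.int64),
        np.array(cols["ref"], dtype=object), np.array(cols["alt"], dtype=object),
        np.array(cols["qual"]), np.array(cols["qd"]), np.array(cols["fs"]),
        np.array(cols["rprs"]), np.array(cols["dp"]),
        np.array(gts, dtype=np.int8).reshape(n, len(samples)),
        samples,
        sample_dp=np.array(dps, dtype=np.int32).reshape(n, len(samples)) if have_fmt_dp and dps else None,
        provenance=prov,
    )


def _format_headers(vcf) -> list[dict]:
    out = []
    for h in vcf.header_iter():
        try:
            if h["HeaderType"] == "FORMAT":
                out.append(h)
        except KeyError:
            continue
    return out


def _info_float(v, key: str) -> float:
    val = v.INFO.get(key)
    return np.nan if val is None else float(val)


# ---------------------------------------------------------------------------
# writing


def write_vcf(table: VariantTable, path: str | Path) -> None:
    """Write the table as VCF v4.2 (INFO QD/FS/ReadPosRankSum/DP, FORMAT GT[:DP]).

    Deterministic text output: identical tables produce identical bytes.
    Applied filters are serialized as ``##sweepherd_filter`` header lines.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Variant quality by depth">\n')
        fh.write('##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias (phred)">\n')
        fh.write('##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank-sum Z">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total site depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if table.sample_dp is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Sample depth">\n')
        for chrom in dict.fromkeys(table.chrom.tolist()):
            fh.write(f"##contig=<ID={chrom}>\n")
        for entry in table.provenance:
            body = ";".join(f"{k}={_prov_fmt(v)}" for k, v in entry.items())
            fh.write(f"##sweepherd_filter=<{body}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t" + "FORMAT\t" + "\t".join(table.samples) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        fmt = "GT:DP" if table.sample_dp is not None else "GT"
        for i in range(table.n_sites):
            info = []
            for key, arr in (("QD", table.qd), ("FS", table.fs), ("ReadPosRankSum", table.rprs)):
                if np.isfinite(arr[i]):
                    info.append(f"{key}={arr[i]:.6g}")
            if np.isfinite(table.site_dp[i]):
                info.append(f"DP={int(table.site_dp[i])}")
            qual = f"{table.qual[i]:.6g}" if np.isfinite(table.qual[i]) else "."
            if table.sample_dp is not None:
                cells = [f"{gt_str[int(g)]}:{int(d) if d >= 0 else '.'}"
                         for g, d in zip(table.genotypes[i], table.sample_dp[i])]
            else:
                cells = [gt_str[int(g)] for g in table.genotypes[i]]
            fh.write(
                f"{table.chrom[i]}\t{table.pos[i]}\t.\t{table.ref[i]}\t{table.alt[i]}\t"
                f"{qual}\tPASS\t{';'.join(info) or '.'}\t{fmt}\t" + "\t".join(cells) + "\n"
            )


def _prov_fmt(v) -> str:
    if isinstance(v, dict):
        return "|".join(f"{k}:{x}" for k, x in v.items())
    return str(v)


def write_sites_tsv(table: VariantTable, path: str | Path) -> None:
    """Minimal site list: chrom, pos, ref, alt (one line per record)."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for i in range(table.n_sites):
            fh.write(f"{table.chrom[i]}\t{table.pos[i]}\t{table.ref[i]}\t{table.alt[i]}\n")


def write_filter_report(table: VariantTable, path: str | Path) -> None:
    """Per-rule removal counts from the table's provenance, as TSV."""
    with open(path, "w") as fh:
        fh.write("stage\trule\tremoved\n")
        for entry in table.provenance:
            for rule, count in entry.get("removed", {}).items():
                fh.write(f"{entry['stage']}\t{rule}\t{count}\n")


# ---------------------------------------------------------------------------
# filtering


def split_snps_indels(table: VariantTable) -> tuple[VariantTable, VariantTable]:
    """Partition the table into SNP-only and indel-only tables."""
    snp = table.is_snp
    return (
        table.subset(snp, {"stage": "split", "kept": "snps"}),
        table.subset(~snp, {"stage": "split", "kept": "indels"}),
    )


def filter_snps(snp_table: VariantTable, thresholds: FilterThresholds = FilterThresholds()) -> VariantTable:
    """Apply the SNP exclusion criteria.

    Hard rules (strict inequalities; an absent annotation never fails):
    QD < qd_min, ReadPosRankSum < rprs_min, FS > fs_max, QUAL < qual_min_snp;
    then call rate < max_missing, then MAF < maf_min over all called
    genotypes. A record failing several rules is counted under the first.
    """
    t = snp_table
    th = thresholds
    fails = {
        "qd": t.qd < th.qd_min,
        "rprs": t.rprs < th.rprs_min,
        "fs": t.fs > th.fs_max,
        "qual": t.qual < th.qual_min_snp,
        "missing": t.call_rate() < th.max_missing,
        "maf": t.maf() < th.maf_min,
    }
    return _apply_rules(t, fails, SNP_RULES, "filter_snps")


def filter_indels(indel_table: VariantTable, thresholds: FilterThresholds = FilterThresholds()) -> VariantTable:
    """Apply the indel exclusion criteria.

    Both QUAL floors are applied (the stricter dominates numerically but
    each keeps its own removal count); indels longer than ``max_indel_size``
    (exclusive boundary: 25 bp kept, 26 bp removed) and low-MAF sites drop.
    """
    t = indel_table
    th = thresholds
    fails = {
        "qual20": t.qual < th.qual_min_indel_a,
        "qd": t.qd < th.qd_min,
        "rprs": t.rprs < th.rprs_min,
        "fs": t.fs > th.fs_max,
        "qual": t.qual < th.qual_min_indel_b,
        "size": t.indel_size > th.max_indel_size,
        "maf": t.maf() < th.maf_min,
    }
    return _apply_rules(t, fails, INDEL_RULES, "filter_indels")


def _apply_rules(t: VariantTable, fails: dict[str, np.ndarray], order: tuple[str, ...], stage: str) -> VariantTable:
    # comparisons against NaN are False, so absent metrics never fail a rule
    fail_matrix = np.vstack([np.asarray(fails[r], dtype=bool) for r in order])
    any_fail = fail_matrix.any(axis=0)
    first = np.full(t.n_sites, -1, dtype=np.int64)
    first[any_fail] = fail_matrix[:, any_fail].argmax(axis=0)
    removed = {r: int((first == k).sum()) for k, r in enumerate(order)}
    entry = {"stage": stage, "input": t.n_sites, "removed": removed, "survivors": int((~any_fail).sum())}
    return t.subset(~any_fail, entry)
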