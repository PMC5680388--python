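"""Cohort QC and diversity summaries.

Implements the per-cohort quality numbers a resequencing study reports after
filtration: transition/transversion ratio, heterozygous/homozygous genotype
ratios, windowless nucleotide diversity (theta-pi), per-chromosome SNP
density, site-depth range, the signed indel-length spectrum, cross-population
variant sharing (Venn cells) and novelty against a known-sites list.

Nucleotide diversity uses the unbiased frequency estimator

    theta_pi = sum_s [n_s / (n_s - 1)] * 2 p_s (1 - p_s) / span_bp

with ``n_s`` the called chromosomes and ``p_s`` the alt frequency at site
``s``; this equals the exact mean pairwise difference between the sampled
chromosomes, averaged over the span.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .popmap import PopulationMap
from .vcfio import MISSING, VariantTable

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class SharingSummary:
    """Cross-population presence patterns of variants."""

    populations: list[str]
    venn_cells: dict[tuple[str, ...], int]  # exact presence pattern -> count
    population_specific: dict[str, int]
    shared_by_all: int
    total: int

    @property
    def shared_by_all_fraction(self) -> float:
        return self.shared_by_all / self.total if self.total else 0.0


def titv_ratio(snp_table: VariantTable) -> float:
    """Transition/transversion ratio; NaN when there are no transversions."""
    ti = tv = 0
    for r, a in zip(snp_table.ref, snp_table.alt):
        if (r, a) in TRANSITIONS:
            ti += 1
        else:
            tv += 1
    return ti / tv if tv else float("nan")


def het_hom_ratio(table: VariantTable, scope: str = "sample",
                  popmap: PopulationMap | None = None) -> dict[str, float]:
    """Heterozygous / homozygous-alt genotype counts per sample or population.

    Missing genotypes are excluded; a scope with zero hom-alt genotypes gets
    NaN. Population scope pools the genotypes of its samples.
    """
    g = table.genotypes
    if scope == "sample":
        groups = {s: [i] for i, s in enumerate(table.samples)}
    elif scope == "population":
        if popmap is None:
            raise ValueError("population scope requires a population map")
        groups = {p: popmap.indices_in(p, table.samples) for p in popmap.populations}
    else:
        raise ValueError(f"unknown scope {scope!r}")
    out = {}
    for name, idx in groups.items():
        sub = g[:, idx]
        het = int((sub == 1).sum())
        hom = int((sub == 2).sum())
        out[name] = het / hom if hom else float("nan")
    return out


def nucleotide_diversity(table: VariantTable, population: str | None,
                         span_bp: float, popmap: PopulationMap | None = None) -> float:
    """Per-bp theta-pi of a population (or the whole cohort) over span_bp.

    Sites with fewer than two called chromosomes are skipped; monomorphic
    positions contribute zero but the span still covers them.
    """
    if span_bp <= 0:
        raise ValueError("span_bp must be positive")
    if population is None:
        idx = None
    else:
        if popmap is None:
            raise ValueError("population selection requires a population map")
        idx = popmap.indices_in(population, table.samples)
    return float(per_site_pi(table, idx).sum() / span_bp)


def per_site_pi(table: VariantTable, sample_idx: list[int] | None = None) -> np.ndarray:
    """Unbiased per-site pairwise-difference contribution, one value per record."""
    g = table.genotypes if sample_idx is None else table.genotypes[:, sample_idx]
    called = g != MISSING
    n = 2 * called.sum(axis=1).astype(np.float64)
    alt = np.where(called, g, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / n
        pi = n / (n - 1.0) * 2.0 * p * (1.0 - p)
    pi[n < 2] = 0.0
    return np.nan_to_num(pi, nan=0.0)


def snp_density_per_chromosome(table: VariantTable, chrom_lengths: dict[str, int]):
    """Per-chromosome SNP count and per-bp density as a DataFrame."""
    import pandas as pd

    counts = Counter(table.chrom.tolist())
    rows = [
        {"chrom": c, "length_bp": L, "n_snps": counts.get(c, 0), "density_per_bp": counts.get(c, 0) / L}
        for c, L in chrom_lengths.items()
    ]
    return pd.DataFrame(rows)


def site_depth_summary(table: VariantTable) -> tuple[float, float, float]:
    """(min, max, mean) of site depth over records with a DP annotation."""
    dp = table.site_dp[np.isfinite(table.site_dp)]
    if dp.size == 0:
        return (float("nan"),) * 3
    return float(dp.min()), float(dp.max()), float(dp.mean())


def indel_length_spectrum(indel_table: VariantTable) -> dict[int, int]:
    """Signed length histogram: insertions positive, deletions negative."""
    hist: Counter[int] = Counter()
    for r, a in zip(indel_table.ref, indel_table.alt):
        delta = len(a) - len(r)
        if delta != 0:
            hist[delta] += 1
    return dict(sorted(hist.items()))


def population_sharing(table: VariantTable, popmap: PopulationMap) -> SharingSummary:
    """Venn decomposition of variant presence across populations.

    A variant is present in a population when at least one called genotype
    there carries an alt allele (dosage >= 1).
    """
    pops = popmap.populations
    if len(pops) < 2:
        raise ValueError("sharing requires at least two populations")
    presence = np.zeros((table.n_sites, len(pops)), dtype=bool)
    for k, pop in enumerate(pops):
        idx = popmap.indices_in(pop, table.samples)
        presence[:, k] = (table.genotypes[:, idx] >= 1).any(axis=1)
    cells: Counter[tuple[str, ...]] = Counter()
    for row in presence:
        pattern = tuple(p for p, flag in zip(pops, row) if flag)
        cells[pattern] += 1
    specific = {p: cells.get((p,), 0) for p in pops}
    return SharingSummary(
        populations=pops,
        venn_cells=dict(cells),
        population_specific=specific,
        shared_by_all=cells.get(tuple(pops), 0),
        total=table.n_sites,
    )


def novelty_vs_known(table: VariantTable, known_sites) -> tuple[int, int]:
    """(novel, known) counts by exact (chrom, pos, ref, alt) match.

    ``known_sites`` is an iterable of 4-tuples or a path to a 4-column TSV.
    """
    if isinstance(known_sites, (str, Path)):
        known = set()
        for line in Path(known_sites).read_text().splitlines():
            if not line.strip() or line.startswith(("#", "chrom\t")):
                continue
            c, p, r, a = line.rstrip("\n").split("\t")[:4]
            known.add((c, int(p), r, a))
    else:
        known = {(c, int(p), r, a) for c, p, r, a in known_sites}
    n_known = sum(
        (c, int(p), r, a) in known
        for c, p, r, a in zip(table.chrom, table.pos, table.ref, table.alt)
    )
    return table.n_sites - n_known, n_known
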