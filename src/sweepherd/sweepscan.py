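"""Windowed selective-sweep scan: FST x log2 nucleotide-diversity ratio.

The scan contrasts a target population set against a reference set in
sliding windows (default 100 kb, 10 kb step):

* per-site Weir & Cockerham (1984) variance components a (between
  populations), b (between individuals within populations) and c (within
  individuals), combined per window as the ratio of sums
  FST_window = sum(a) / sum(a + b + c);
* windowed theta-pi per group (unbiased frequency estimator over the
  realized window span) and the log2 of their ratio;
* empirical-tail thresholds: each statistic's cutoff is an empirical
  quantile of the unmasked window values (right tail for FST; right tail of
  the log2 ratio by default — "figure4" direction — or the left tail with
  ``direction="depleted"``, the classic diversity-depletion expectation);
* windows exceeding both cutoffs are merged (overlapping or bookended) into
  candidate regions and annotated with overlapping genes.

Negative per-window FST values are retained in the empirical distribution;
clamping would distort the quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .popmap import PopulationMap
from .varannot import GeneModel
from .varstats import per_site_pi
from .vcfio import MISSING, VariantTable


@dataclass
class ScanConfig:
    """Window geometry, tail fractions and the population contrast."""

    window_bp: int = 100_000
    step_bp: int = 10_000
    tail: float = 0.05
    min_snps_per_window: int = 10
    target: list[str] = field(default_factory=list)
    reference: list[str] = field(default_factory=list)
    direction: str = "figure4"  # "figure4": right tail of log2 ratio; "depleted": left tail

    def __post_init__(self):
        if self.window_bp <= 0 or self.step_bp <= 0:
            raise ValueError("window and step must be positive")
        if self.step_bp > self.window_bp:
            import warnings

            warnings.warn("step larger than window leaves uncovered gaps")
        if not 0.0 < self.tail < 0.5:
            raise ValueError("tail must be in (0, 0.5)")
        if self.direction not in ("figure4", "depleted"):
            raise ValueError("direction must be 'figure4' or 'depleted'")


@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    n_windows: int
    max_fst: float
    max_abs_log2_ratio: float
    genes: list[str] = field(default_factory=list)


def make_windows(chrom_lengths: dict[str, int], window_bp: int, step_bp: int) -> pd.DataFrame:
    """Sliding windows: starts every step_bp while start < length, ends truncated."""
    rows = []
    for chrom, L in chrom_lengths.items():
        start = 0
        while start < L:
            rows.append((chrom, start, min(start + window_bp, L)))
            start += step_bp
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) variance components, two populations, diploid


def site_fst_components(table: VariantTable, target_idx, reference_idx) -> pd.DataFrame:
    """Per-site WC84 components for the target/reference contrast.

    Returns a DataFrame with columns a, b, c and ``usable``. A site is
    unusable when either population has no called genotypes or when the
    pooled sample is monomorphic (a + b + c = 0).
    """
    stats = []
    for idx in (target_idx, reference_idx):
        g = table.genotypes[:, idx]
        called = g != MISSING
        n_i = called.sum(axis=1).astype(np.float64)  # diploids
        alt = np.where(called, g, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = alt / (2.0 * n_i)
            h_i = np.where(called, g == 1, False).sum(axis=1) / n_i
        stats.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = stats
    a, b, c = wc84_components(n1, p1, h1, n2, p2, h2)
    with np.errstate(invalid="ignore"):
        usable = (n1 >= 1) & (n2 >= 1) & np.isfinite(a + b + c) & ((a + b + c) != 0.0)
    out = pd.DataFrame({
        "chrom": table.chrom, "pos": table.pos,
        "a": a, "b": b, "c": c, "usable": usable,
    })
    return out


def wc84_components(n1, p1, h1, n2, p2, h2):
    """WC84 a/b/c for two diploid populations, vectorized.

    ``n_i``: called diploid counts; ``p_i``: alt-allele frequencies;
    ``h_i``: observed heterozygote proportions.
    """
    n1 = np.asarray(n1, dtype=np.float64)
    n2 = np.asarray(n2, dtype=np.float64)
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = (n1 + n2) / r
        n_c = (r * n_bar - (n1 ** 2 + n2 ** 2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (1.0 / (n_bar - 1.0)) * (p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2 - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
        )
        c = h_bar / 2.0
    return a, b, c


def weighted_fst(components: pd.DataFrame) -> float:
    """Genome-wide ratio-of-sums FST over usable sites."""
    u = components[components["usable"]]
    denom = (u["a"] + u["b"] + u["c"]).sum()
    return float(u["a"].sum() / denom) if denom != 0 else float("nan")


# ---------------------------------------------------------------------------
# windowed statistics


def window_scan(
    table: VariantTable,
    popmap: PopulationMap,
    chrom_lengths: dict[str, int],
    config: ScanConfig,
) -> pd.DataFrame:
    """Compute per-window n_snps, group theta-pi, FST and log2 ratio.

    Returns one row per window with a ``masked`` flag for windows below
    ``min_snps_per_window`` usable sites. Window sums are prefix-sum based,
    so overlapping windows share per-site terms consistently.
    """
    t_idx = [i for p in config.target for i in popmap.indices_in(p, table.samples)]
    r_idx = [i for p in config.reference for i in popmap.indices_in(p, table.samples)]
    if not t_idx or not r_idx:
        raise ValueError("target and reference population sets must be non-empty")

    comp = site_fst_components(table, t_idx, r_idx)
    pi_t_site = per_site_pi(table, t_idx)
    pi_r_site = per_site_pi(table, r_idx)
    usable = comp["usable"].to_numpy()
    a = np.where(usable, comp["a"].to_numpy(), 0.0)
    abc = np.where(usable, (comp["a"] + comp["b"] + comp["c"]).to_numpy(), 0.0)

    windows = make_windows(chrom_lengths, config.window_bp, config.step_bp)
    rows = []
    for chrom in chrom_lengths:
        cmask = table.chrom == chrom
        pos = table.pos[cmask]
        order = np.argsort(pos, kind="stable")
        pos = pos[order]

        def prefix(arr):
            vals = arr[cmask][order]
            return np.concatenate([[0.0], np.cumsum(vals)])

        cum_usable = prefix(usable.astype(np.float64))
        cum_a, cum_abc = prefix(a), prefix(abc)
        cum_pit, cum_pir = prefix(pi_t_site), prefix(pi_r_site)

        wsub = windows[windows["chrom"] == chrom]
        # sites with start < pos <= end (pos is 1-based)
        lo = np.searchsorted(pos, wsub["start"].to_numpy(), side="right")
        hi = np.searchsorted(pos, wsub["end"].to_numpy(), side="right")
        for (start, end), i0, i1 in zip(wsub[["start", "end"]].to_numpy(), lo, hi):
            span = end - start
            n_usable = int(cum_usable[i1] - cum_usable[i0])
            sum_a = cum_a[i1] - cum_a[i0]
            sum_abc = cum_abc[i1] - cum_abc[i0]
            pi_t = (cum_pit[i1] - cum_pit[i0]) / span
            pi_r = (cum_pir[i1] - cum_pir[i0]) / span
            fst = sum_a / sum_abc if sum_abc != 0 else np.nan
            if pi_r > 0 and pi_t > 0:
                log2r = np.log2(pi_t / pi_r)
            elif pi_r > 0:
                log2r = -np.inf
            else:
                log2r = np.nan
            rows.append((chrom, start, end, int(i1 - i0), n_usable, pi_t, pi_r, fst, log2r))
    out = pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "n_snps", "n_usable", "pi_target", "pi_reference", "fst", "log2_ratio",
    ])
    out["masked"] = (
        (out["n_usable"] < config.min_snps_per_window)
        | ~np.isfinite(out["fst"])
        | ~np.isfinite(out["log2_ratio"])
    )
    return out


def log2_pi_ratio(pi_target: float, pi_reference: float) -> float:
    """log2(pi_target / pi_reference); -inf when target is 0, NaN when reference is 0."""
    if pi_reference <= 0:
        return float("nan")
    if pi_target <= 0:
        return float("-inf")
    return float(np.log2(pi_target / pi_reference))


def empirical_thresholds(window_stats: pd.DataFrame, tail: float,
                         direction: str = "figure4") -> tuple[float, float]:
    """(fst_cut, ratio_cut) from the empirical window distributions.

    FST uses the right tail (1 - tail quantile). The log2 ratio uses the
    right tail for direction "figure4" and the left tail (tail quantile)
    for "depleted". Quantiles use linear interpolation between order
    statistics.
    """
    unmasked = window_stats[~window_stats["masked"]]
    if len(unmasked) < 1.0 / tail:
        raise ValueError(f"too few unmasked windows ({len(unmasked)}) for tail {tail}")
    fst_cut = float(np.quantile(unmasked["fst"], 1.0 - tail, method="linear"))
    if direction == "depleted":
        ratio_cut = float(np.quantile(unmasked["log2_ratio"], tail, method="linear"))
    else:
        ratio_cut = float(np.quantile(unmasked["log2_ratio"], 1.0 - tail, method="linear"))
    return fst_cut, ratio_cut


def select_windows(window_stats: pd.DataFrame, fst_cut: float, ratio_cut: float,
                   direction: str = "figure4") -> pd.DataFrame:
    """Add a ``selected`` flag: unmasked windows strictly beyond both cuts."""
    out = window_stats.copy()
    if direction == "depleted":
        ratio_pass = out["log2_ratio"] < ratio_cut
    else:
        ratio_pass = out["log2_ratio"] > ratio_cut
    out["selected"] = (~out["masked"]) & (out["fst"] > fst_cut) & ratio_pass
    return out


def select_regions(window_stats: pd.DataFrame) -> list[CandidateRegion]:
    """Merge overlapping or bookended selected windows into candidate regions."""
    sel = window_stats[window_stats["selected"]].sort_values(["chrom", "start"])
    regions: list[CandidateRegion] = []
    for _, w in sel.iterrows():
        if (
            regions
            and regions[-1].chrom == w["chrom"]
            and w["start"] <= regions[-1].end  # overlap or bookended
        ):
            r = regions[-1]
            r.end = max(r.end, int(w["end"]))
            r.n_windows += 1
            r.max_fst = max(r.max_fst, float(w["fst"]))
            r.max_abs_log2_ratio = max(r.max_abs_log2_ratio, abs(float(w["log2_ratio"])))
        else:
            regions.append(CandidateRegion(
                chrom=w["chrom"], start=int(w["start"]), end=int(w["end"]),
                n_windows=1, max_fst=float(w["fst"]),
                max_abs_log2_ratio=abs(float(w["log2_ratio"])),
            ))
    return regions


def annotate_regions_with_genes(regions: list[CandidateRegion],
                                gene_models: list[GeneModel]) -> list[CandidateRegion]:
    """List every gene whose transcript span overlaps a region by >= 1 bp."""
    for r in regions:
        hit = {
            m.gene_id
            for m in gene_models
            if m.chrom == r.chrom and m.tx_start < r.end and m.tx_end > r.start
        }
        r.genes = sorted(hit)
    return regions


def allele_frequency_difference(table: VariantTable, popmap: PopulationMap,
                                target: list[str], reference: list[str]) -> pd.DataFrame:
    """Per-site |delta p| between the target and reference groups."""
    t_idx = [i for p in target for i in popmap.indices_in(p, table.samples)]
    r_idx = [i for p in reference for i in popmap.indices_in(p, table.samples)]
    pt = table.alt_freq(t_idx)
    pr = table.alt_freq(r_idx)
    return pd.DataFrame({
        "chrom": table.chrom, "pos": table.pos,
        "p_target": pt, "p_reference": pr, "abs_diff": np.abs(pt - pr),
    })


def run_scan(
    table: VariantTable,
    popmap: PopulationMap,
    chrom_lengths: dict[str, int],
    config: ScanConfig,
    gene_models: list[GeneModel] | None = None,
) -> tuple[pd.DataFrame, tuple[float, float], list[CandidateRegion]]:
    """Full scan: window stats -> thresholds -> selection -> merged regions."""
    stats = window_scan(table, popmap, chrom_lengths, config)
    cuts = empirical_thresholds(stats, config.tail, config.direction)
    stats = select_windows(stats, *cuts, direction=config.direction)
    regions = select_regions(stats)
    if gene_models is not None:
        regions = annotate_regions_with_genes(regions, gene_models)
    return stats, cuts, regions
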