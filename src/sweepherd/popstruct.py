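"""Population structure: distances, NJ tree, PCA, LD and pairwise FST.

* p-distance between individuals from unphased dosages: the mean per-allele
  difference over sites called in both samples,
  d(i,j) = sum_s |g_is - g_js| / (2 m_ij).
* Neighbor-joining (Saitou & Nei) on the distance matrix, with a
  deterministic lexicographic tie-break and optional rooting on a named
  outgroup; Newick output.
* PCA of the genotype matrix under the GCTA/Patterson convention: center by
  2 p-hat, scale by sqrt(2 p-hat (1 - p-hat)), missing values imputed to the
  site mean, GRM = X X^T / m, dense eigendecomposition.
* Genotypic (composite) LD r^2 between dosage vectors, binned decay curve,
  and PLINK indep-pairwise style thinning (window/step in SNP counts).
* Pairwise population FST: genome-wide ratio-of-sums Weir-Cockerham
  estimates for every population pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .popmap import PopulationMap
from .sweepscan import site_fst_components, weighted_fst
from .vcfio import MISSING, VariantTable


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal, values in [0, 1]
    n_sites: np.ndarray  # per-pair co-called site counts

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix must be symmetric")


@dataclass
class LDResult:
    pairs: pd.DataFrame  # chrom, pos_a, pos_b, dist_bp, r2
    n_skipped: int  # pairs skipped for zero variance


# ---------------------------------------------------------------------------
# distances + NJ


def pairwise_p_distance(table: VariantTable) -> DistanceMatrix:
    """Allele-sharing p-distance between all sample pairs."""
    n = table.n_samples
    if n < 2:
        raise ValueError("need at least two samples")
    g = table.genotypes.astype(np.float64)
    g[table.genotypes == MISSING] = np.nan
    d = np.zeros((n, n))
    m = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        diff = np.abs(g[:, i:i + 1] - g[:, i + 1:])  # sites x (n-i-1)
        ok = np.isfinite(diff)
        cnt = ok.sum(axis=0)
        for k, j in enumerate(range(i + 1, n)):
            if cnt[k] == 0:
                raise ValueError(f"no co-called sites for pair ({table.samples[i]}, {table.samples[j]})")
            dij = np.nansum(diff[:, k]) / (2.0 * cnt[k])
            d[i, j] = d[j, i] = dij
            m[i, j] = m[j, i] = cnt[k]
    return DistanceMatrix(list(table.samples), d, m)


def nj_tree(dist: DistanceMatrix, outgroup: str | None = None) -> str:
    """Saitou-Nei neighbor joining; returns a Newick string.

    Ties in the Q criterion break toward the lexicographically smallest pair
    of current node labels, making the output deterministic. The tree is
    unrooted (trifurcation at the final join); with an outgroup it is rooted
    at the midpoint of the outgroup's pendant edge.
    """
    n = len(dist.ids)
    if n < 3:
        raise ValueError("NJ requires at least three taxa")
    if outgroup is not None and outgroup not in dist.ids:
        raise ValueError(f"outgroup {outgroup!r} not among taxa")

    # active nodes are ids into an adjacency map; leaves carry their names
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n)}
    names: dict[int, str] = dict(enumerate(dist.ids))
    active = list(range(n))
    labels = {i: dist.ids[i] for i in range(n)}  # tie-break labels
    D = {(i, j): float(dist.matrix[i, j]) for i in range(n) for j in range(n)}
    next_id = n

    def d(i, j):
        return D[(i, j)] if i <= j else D[(j, i)]

    while len(active) > 3:
        m = len(active)
        row = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        for ii, i in enumerate(active):
            for j in active[ii + 1:]:
                q = (m - 2) * d(i, j) - row[i] - row[j]
                key = (q, *sorted((labels[i], labels[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = d(i, j)
        li = 0.5 * dij + (row[i] - row[j]) / (2.0 * (m - 2))
        lj = dij - li
        u = next_id
        next_id += 1
        adj[u] = [(i, li), (j, lj)]
        adj[i].append((u, li))
        adj[j].append((u, lj))
        for k in active:
            if k not in (i, j):
                D[tuple(sorted((u, k)))] = 0.5 * (d(i, k) + d(j, k) - dij)
        active = [k for k in active if k not in (i, j)] + [u]
        labels[u] = min(labels[i], labels[j])
        names[u] = ""

    # final trifurcation (or the 3-taxon closed form)
    i, j, k = active
    li = 0.5 * (d(i, j) + d(i, k) - d(j, k))
    lj = 0.5 * (d(i, j) + d(j, k) - d(i, k))
    lk = 0.5 * (d(i, k) + d(j, k) - d(i, j))
    center = next_id
    adj[center] = [(i, li), (j, lj), (k, lk)]
    for node, bl in adj[center]:
        adj[node].append((center, bl))

    if outgroup is None:
        return _newick_from(center, None, adj, names) + ";"
    og = dist.ids.index(outgroup)
    (nbr, bl) = adj[og][0]
    left = _newick_leaf_or_sub(og, nbr, adj, names)
    right = _newick_from(nbr, og, adj, names)
    return f"({left}:{bl / 2.0:.10g},{right}:{bl / 2.0:.10g});"


def _newick_leaf_or_sub(node, parent, adj, names):
    return names[node] if names[node] else _newick_from(node, parent, adj, names)


def _newick_from(node: int, parent: int | None, adj, names) -> str:
    children = [(c, bl) for c, bl in adj[node] if c != parent]
    if not children:
        return names[node]
    parts = [f"{_newick_from(c, node, adj, names)}:{bl:.10g}" for c, bl in children]
    return "(" + ",".join(parts) + ")"


# ---------------------------------------------------------------------------
# PCA


def pca(table: VariantTable, k: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """GRM eigendecomposition; returns (eigenvectors n x k, eigenvalues k).

    Eigenvalues are sorted descending; eigenvectors are GRM eigenvectors
    (sample loadings). Monomorphic sites are dropped; if none remain, raises.
    """
    g = table.genotypes.astype(np.float64)
    g[table.genotypes == MISSING] = np.nan
    p_hat = np.nanmean(g, axis=1) / 2.0
    poly = np.isfinite(p_hat) & (p_hat > 0) & (p_hat < 1)
    if not poly.any():
        raise ValueError("no polymorphic sites for PCA")
    g = g[poly]
    p_hat = p_hat[poly]
    x = (g - 2.0 * p_hat[:, None]) / np.sqrt(2.0 * p_hat * (1.0 - p_hat))[:, None]
    x = np.nan_to_num(x, nan=0.0)  # missing -> site mean after centering
    grm = x.T @ x / x.shape[0]
    vals, vecs = np.linalg.eigh(grm)
    order = np.argsort(vals)[::-1][:k]
    return vecs[:, order], vals[order]


# ---------------------------------------------------------------------------
# linkage disequilibrium


def _row_vs_block_r2(x: np.ndarray, block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete squared Pearson correlation of one dosage row
    against a block of rows. Returns (r2, valid); invalid pairs have fewer
    than two co-called samples or a zero-variance member."""
    mx = np.isfinite(x)
    mb = np.isfinite(block)
    both = mx & mb
    n = both.sum(axis=1).astype(np.float64)
    x0 = np.where(mx, x, 0.0)
    b0 = np.where(mb, block, 0.0)
    sx = (both * x0).sum(axis=1)
    sy = (both * b0).sum(axis=1)
    sxy = (b0 * x0).sum(axis=1)
    sxx = (both * x0 ** 2).sum(axis=1)
    syy = (b0 ** 2 * mx).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx ** 2
        vary = n * syy - sy ** 2
        r2 = cov ** 2 / (varx * vary)
    valid = (n >= 2) & (varx > 0) & (vary > 0)
    return np.where(valid, r2, np.nan), valid


def ld_r2(table: VariantTable, max_bp: int = 1_000_000) -> LDResult:
    """Composite r^2 for intra-chromosomal SNP pairs within max_bp.

    r^2 is the squared Pearson correlation of dosage vectors over samples
    called at both sites; pairs with a zero-variance member are skipped and
    counted. All values are kept (no r^2 floor).
    """
    g = table.genotypes.astype(np.float64)
    g[table.genotypes == MISSING] = np.nan
    rows = []
    n_skipped = 0
    for chrom in dict.fromkeys(table.chrom.tolist()):
        cmask = table.chrom == chrom
        pos = table.pos[cmask]
        sub = g[cmask]
        for i in range(len(pos)):
            j_hi = np.searchsorted(pos, pos[i] + max_bp, side="right")
            if j_hi <= i + 1:
                continue
            r2, valid = _row_vs_block_r2(sub[i], sub[i + 1:j_hi])
            n_skipped += int((~valid).sum())
            for off in np.flatnonzero(valid):
                j = i + 1 + off
                rows.append((chrom, int(pos[i]), int(pos[j]), int(pos[j] - pos[i]), float(r2[off])))
    pairs = pd.DataFrame(rows, columns=["chrom", "pos_a", "pos_b", "dist_bp", "r2"])
    return LDResult(pairs, n_skipped)


def ld_decay(ld: LDResult, bin_bp: int) -> pd.DataFrame:
    """Mean r^2 per distance bin (bin label = left edge)."""
    if ld.pairs.empty:
        return pd.DataFrame(columns=["bin_bp", "mean_r2", "n_pairs"])
    bins = (ld.pairs["dist_bp"] // bin_bp) * bin_bp
    agg = ld.pairs.groupby(bins)["r2"].agg(["mean", "size"]).reset_index()
    agg.columns = ["bin_bp", "mean_r2", "n_pairs"]
    return agg


def ld_thin(table: VariantTable, window: int = 50, step: int = 5, r2_max: float = 0.5) -> VariantTable:
    """PLINK indep-pairwise style thinning on SNP-count windows.

    Within each window of ``window`` SNPs (advanced by ``step``), any pair of
    surviving SNPs with r^2 > r2_max loses its later-positioned member;
    chromosomes are processed independently.
    """
    g = table.genotypes.astype(np.float64)
    g[table.genotypes == MISSING] = np.nan
    keep = np.ones(table.n_sites, dtype=bool)
    offsets = np.arange(table.n_sites)
    for chrom in dict.fromkeys(table.chrom.tolist()):
        cidx = offsets[table.chrom == chrom]
        start = 0
        while start < len(cidx):
            widx = cidx[start:start + window]
            alive = [i for i in widx if keep[i]]
            if len(alive) > 1:
                r2m = _window_r2_matrix(g[alive])
                for ai in range(len(alive)):
                    if not keep[alive[ai]]:
                        continue
                    for aj in range(ai + 1, len(alive)):
                        j = alive[aj]
                        if keep[j] and r2m[ai, aj] > r2_max:
                            keep[j] = False  # drop the later-positioned SNP
            if start + window >= len(cidx):
                break
            start += step
    return table.subset(keep, {"stage": "ld_thin", "survivors": int(keep.sum()),
                               "removed": {"r2": int((~keep).sum())}})


def _window_r2_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise-complete r^2 matrix for a small window of dosage rows;
    invalid pairs (zero variance or <2 co-called samples) are NaN."""
    M = np.isfinite(X)
    X0 = np.where(M, X, 0.0)
    Mf = M.astype(np.float64)
    n = Mf @ Mf.T
    sx = X0 @ Mf.T  # sum of row i over samples co-called with row j
    sxy = X0 @ X0.T
    sxx = (X0 ** 2) @ Mf.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        varx = n * sxx - sx ** 2
        r2 = cov ** 2 / (varx * varx.T)
    r2[(n < 2) | (varx <= 0) | (varx.T <= 0)] = np.nan
    return r2


# ---------------------------------------------------------------------------
# pairwise population FST


def pairwise_population_fst(table: VariantTable, popmap: PopulationMap) -> pd.DataFrame:
    """Genome-wide weighted WC84 FST for every population pair."""
    pops = popmap.populations
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, p1 in enumerate(pops):
        for p2 in pops[i + 1:]:
            comp = site_fst_components(
                table, popmap.indices_in(p1, table.samples), popmap.indices_in(p2, table.samples)
            )
            fst = weighted_fst(comp)
            mat.loc[p1, p2] = mat.loc[p2, p1] = fst
    return mat
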