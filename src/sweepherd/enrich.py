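"""Over-representation analysis: hypergeometric test + Benjamini-Hochberg FDR.

For each term with K background genes, the probability that a candidate set
of n genes contains k or more term members by chance is the hypergeometric
upper tail P[X >= k], X ~ Hypergeom(N, K, n) over a background of N genes.
The tail is computed by exact summation in log space (log-gamma binomials),
so tiny p-values keep full relative precision. Multiple testing is handled
by the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import gammaln


@dataclass
class EnrichmentRow:
    term_id: str
    term_name: str
    k: int  # candidate genes in term
    K: int  # background genes in term
    n: int  # candidate set size
    N: int  # background size
    p: float
    q: float = float("nan")
    members: list[str] = field(default_factory=list)


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n), exact log-space summation."""
    if k <= 0:
        return 1.0
    hi = min(K, n)
    if k > hi:
        return 0.0
    xs = np.arange(k, hi + 1)
    log_terms = _log_comb(K, xs) + _log_comb(N - K, n - xs) - _log_comb(N, n)
    peak = log_terms.max()
    return float(min(1.0, np.exp(peak) * np.exp(log_terms - peak).sum()))


def hypergeom_enrich(
    candidates: list[str],
    term_map: dict[str, list[tuple[str, str]]] | str | Path,
    background: list[str] | None = None,
) -> list[EnrichmentRow]:
    """Test every term for over-representation in the candidate gene set.

    ``term_map`` maps gene -> [(term_id, term_name), ...] or is a path to a
    3-column TSV (gene, term_id, term_name). The background defaults to all
    genes in the term map; candidates must be a subset of it. Terms with no
    background member are dropped before testing. Rows are sorted by p, then
    term id.
    """
    if isinstance(term_map, (str, Path)):
        term_map = read_term_map(term_map)
    if background is None:
        background = sorted(term_map)
    bg = set(background)
    cand = sorted(set(candidates))
    if not cand:
        raise ValueError("empty candidate set")
    missing = [g for g in cand if g not in bg]
    if missing:
        raise ValueError(f"candidate genes absent from background: {missing}")

    terms: dict[str, tuple[str, set[str]]] = {}
    for gene, annots in term_map.items():
        if gene not in bg:
            continue
        for term_id, term_name in annots:
            terms.setdefault(term_id, (term_name, set()))[1].add(gene)

    N, n = len(bg), len(cand)
    cand_set = set(cand)
    rows = []
    for term_id, (term_name, genes) in terms.items():
        K = len(genes)
        if K == 0:
            continue
        members = sorted(genes & cand_set)
        k = len(members)
        p = hypergeom_upper_tail(k, N, K, n)
        rows.append(EnrichmentRow(term_id, term_name, k, K, n, N, p, members=members))
    rows.sort(key=lambda r: (r.p, r.term_id))
    qs = bh_fdr([r.p for r in rows])
    for r, q in zip(rows, qs):
        r.q = q
    return rows


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, input order preserved."""
    p = np.asarray(p_values, dtype=np.float64)
    m = len(p)
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def read_term_map(path: str | Path) -> dict[str, list[tuple[str, str]]]:
    out: dict[str, list[tuple[str, str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        gene, term_id = f[0], f[1]
        term_name = f[2] if len(f) > 2 else term_id
        out.setdefault(gene, []).append((term_id, term_name))
    return out


def write_enrichment_tsv(rows: list[EnrichmentRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("term_id\tterm_name\tk\tK\tn\tN\tp\tq\tmembers\n")
        for r in rows:
            fh.write(f"{r.term_id}\t{r.term_name}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                     f"{r.p:.6g}\t{r.q:.6g}\t{','.join(r.members)}\n")
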