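"""Independent reference computations used to validate the package.

Each oracle is coded from the published definition through a different
algebraic route than the library implementation, so agreement is evidence
of correctness rather than repetition.
"""

from __future__ import annotations

import itertools
import math


def wc84_direct(n1, p1, h1, n2, p2, h2):
    """Scalar transcription of the Weir & Cockerham (1984) a/b/c equations
    for r=2 diploid populations (sample sizes in diploids, alt frequencies,
    observed heterozygote proportions)."""
    r = 2.0
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1 * n1 + n2 * n2) / (r * n_bar)) / (r - 1.0)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - 1.0 / (n_bar - 1.0) * (p_bar * (1.0 - p_bar) - (r - 1.0) / r * s2 - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1.0 - p_bar) - (r - 1.0) / r * s2 - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar
    )
    c = h_bar / 2.0
    return a, b, c


def wc84_anova(dosages1, dosages2):
    """The same variance components via the ANOVA mean-squares route
    (sums of squares over gene copies grouped as alleles-within-individuals-
    within-populations, with their degrees of freedom), from called diploid
    dosage lists. Algebraically equivalent to the direct expansion but coded
    independently of it."""
    r = 2
    pops = [list(dosages1), list(dosages2)]
    n_i = [len(d) for d in pops]
    n_tot = sum(n_i)
    p_i = [sum(d) / (2.0 * n) for d, n in zip(pops, n_i)]
    p_bar = sum(sum(d) for d in pops) / (2.0 * n_tot)
    n_c = (n_tot - sum(n * n for n in n_i) / n_tot) / (r - 1.0)

    # within-individual SS: 0.5 per heterozygote
    ssg = sum(0.5 for d in pops for g in d if g == 1)
    # between individuals within populations: 2 * sum (g/2 - p_i)^2
    ssi = 2.0 * sum((g / 2.0 - p) ** 2 for d, p in zip(pops, p_i) for g in d)
    # between populations: 2 * sum n_i (p_i - p_bar)^2
    ssp = 2.0 * sum(n * (p - p_bar) ** 2 for n, p in zip(n_i, p_i))

    msg = ssg / n_tot
    msi = ssi / (n_tot - r)
    msp = ssp / (r - 1.0)

    c = msg
    b = (msi - msg) / 2.0
    a = (msp - msi) / (2.0 * n_c)
    return a, b, c


def bruteforce_pi(haplotypes: list[str | list[int]], span_bp: float) -> float:
    """Mean pairwise difference over all chromosome pairs, per bp."""
    n = len(haplotypes)
    total = 0
    pairs = 0
    for i, j in itertools.combinations(range(n), 2):
        total += sum(a != b for a, b in zip(haplotypes[i], haplotypes[j]))
        pairs += 1
    return total / pairs / span_bp


def bruteforce_hypergeom_upper(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] by exhaustive enumeration of all C(N, n) draws (N <= 12)."""
    hits = 0
    total = 0
    items = [1] * K + [0] * (N - K)
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(items[i] for i in draw) >= k:
            hits += 1
    return hits / total


def patristic_distances(newick: str, taxa: list[str]):
    """Leaf-to-leaf path lengths of a Newick tree, via dendropy."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    dist = {}
    for t1, t2 in itertools.combinations(taxa, 2):
        a = tree.taxon_namespace.get_taxon(t1)
        b = tree.taxon_namespace.get_taxon(t2)
        dist[frozenset((t1, t2))] = pdm.patristic_distance(a, b)
    return dist
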