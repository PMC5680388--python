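"""Distances, neighbor joining, PCA, LD and pairwise population FST."""

import numpy as np
import pytest

from sweepherd.popmap import PopulationMap
from sweepherd.popstruct import (
    DistanceMatrix,
    ld_decay,
    ld_r2,
    ld_thin,
    nj_tree,
    pairwise_p_distance,
    pairwise_population_fst,
    pca,
)

from _oracles import patristic_distances
from conftest import make_table


# ---------------------------------------------------------------------------
# p-distance


def test_p_distance_identical_and_opposite():
    t = make_table([
        {"pos": 1, "genotypes": [0, 0, 2]},
        {"pos": 2, "genotypes": [2, 2, 0]},
        {"pos": 3, "genotypes": [1, 1, 1]},
    ], ["x", "y", "z"])
    d = pairwise_p_distance(t)
    assert d.matrix[0, 1] == 0.0
    # x vs z: |0-2| + |2-0| + |1-1| = 4 over 2*3 sites
    assert d.matrix[0, 2] == pytest.approx(4 / 6)


def test_p_distance_opposite_homozygotes_is_one():
    t = make_table([{"pos": i, "genotypes": [0, 2]} for i in (1, 2, 3)], ["x", "y"])
    assert pairwise_p_distance(t).matrix[0, 1] == 1.0


def test_p_distance_missing_pair_errors():
    t = make_table([{"pos": 1, "genotypes": [0, -1]}], ["x", "y"])
    with pytest.raises(ValueError, match="x.*y"):
        pairwise_p_distance(t)


# ---------------------------------------------------------------------------
# neighbor joining


def _additive_matrix_4():
    # tree ((A:1,B:2):1,(C:3,D:4)); internal edge length 1
    ids = ["A", "B", "C", "D"]
    d = {("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
         ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7}
    m = np.zeros((4, 4))
    for (i, j), v in d.items():
        a, b = ids.index(i), ids.index(j)
        m[a, b] = m[b, a] = v
    return DistanceMatrix(ids, m, np.ones((4, 4), dtype=np.int64))


def test_nj_recovers_additive_four_taxon_tree():
    dm = _additive_matrix_4()
    nwk = nj_tree(dm)
    pat = patristic_distances(nwk, dm.ids)
    for i, ti in enumerate(dm.ids):
        for j in range(i + 1, 4):
            assert pat[frozenset((ti, dm.ids[j]))] == pytest.approx(dm.matrix[i, j], abs=1e-9)


def test_nj_three_taxon_closed_form():
    ids = ["A", "B", "C"]
    m = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
    nwk = nj_tree(DistanceMatrix(ids, m, np.ones((3, 3), dtype=np.int64)))
    # pendant branch of A: (dAB + dAC - dBC) / 2 = 0.1
    assert ":0.1" in nwk
    pat = patristic_distances(nwk, ids)
    assert pat[frozenset(("A", "B"))] == pytest.approx(0.3, abs=1e-12)
    assert pat[frozenset(("B", "C"))] == pytest.approx(0.6, abs=1e-12)


def test_nj_six_taxon_additive_tree_via_dendropy_simulation():
    """Distances measured on a random tree are recovered exactly."""
    import dendropy

    nwk_in = "((A:0.10,B:0.20):0.05,((C:0.30,D:0.15):0.08,E:0.25):0.04,F:0.40);"
    tree = dendropy.Tree.get(data=nwk_in, schema="newick")
    taxa = [t.label for t in tree.taxon_namespace]
    pdm = tree.phylogenetic_distance_matrix()
    n = len(taxa)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(tree.taxon_namespace[i], tree.taxon_namespace[j])
            m[i, j] = m[j, i] = d
    nwk_out = nj_tree(DistanceMatrix(taxa, m, np.ones((n, n), dtype=np.int64)))
    pat = patristic_distances(nwk_out, taxa)
    for i in range(n):
        for j in range(i + 1, n):
            assert pat[frozenset((taxa[i], taxa[j]))] == pytest.approx(m[i, j], abs=1e-9)


def test_nj_outgroup_rooting_preserves_path_lengths():
    dm = _additive_matrix_4()
    nwk = nj_tree(dm, outgroup="D")
    assert nwk.startswith("(D:")
    pat = patristic_distances(nwk, dm.ids)
    assert pat[frozenset(("A", "D"))] == pytest.approx(6.0, abs=1e-9)


def test_nj_requires_three_taxa_and_symmetry():
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix(["A", "B"], np.zeros((2, 2)), np.ones((2, 2))))
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(["A", "B", "C"], np.array([[0, 1, 2], [1, 0, 3], [2, 4, 0.0]]),
                       np.ones((3, 3)))


def test_nj_agrees_with_skbio_on_generic_matrix():
    """Independent library cross-check on a random (non-additive) matrix."""
    import skbio

    rng = np.random.default_rng(4)
    n = 7
    ids = [f"t{i}" for i in range(n)]
    m = rng.uniform(0.1, 1.0, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    ours = nj_tree(DistanceMatrix(ids, m, np.ones((n, n))))
    theirs = skbio.tree.nj(skbio.DistanceMatrix(m, ids))
    pat_ours = patristic_distances(ours, ids)
    for i in range(n):
        for j in range(i + 1, n):
            d = theirs.find(ids[i]).distance(theirs.find(ids[j]))
            assert pat_ours[frozenset((ids[i], ids[j]))] == pytest.approx(d, abs=1e-8)


def test_nj_ultrametric_tie_break_deterministic():
    ids = list("ABCD")
    m = np.ones((4, 4)) - np.eye(4)
    dm = DistanceMatrix(ids, m, np.ones((4, 4)))
    assert nj_tree(dm) == nj_tree(dm)


# ---------------------------------------------------------------------------
# PCA


def _balding_nichols_table(seed, f=0.3, n_per_pop=20, n_sites=5000):
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.1, 0.9, size=n_sites)
    c = (1 - f) / f
    g = []
    for _ in range(2):
        p = rng.beta(p_anc * c, (1 - p_anc) * c)
        g.append(rng.binomial(2, p[:, None], size=(n_sites, 2 * n_per_pop // 2)))
    genotypes = np.hstack(g).astype(np.int8)
    samples = [f"A{i}" for i in range(n_per_pop)] + [f"B{i}" for i in range(n_per_pop)]
    records = [{"pos": i + 1, "genotypes": genotypes[i].tolist()} for i in range(n_sites)]
    pm = PopulationMap({s: s[0] for s in samples})
    return make_table(records, samples), pm


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_pca_separates_balding_nichols_populations(seed):
    t, pm = _balding_nichols_table(seed)
    vecs, vals = pca(t, k=2)
    pc1 = vecs[:, 0]
    a = pc1[:20]
    b = pc1[20:]
    assert max(a.min(), b.min()) > min(a.max(), b.max()) or a.max() < b.min() or b.max() < a.min()


def test_pca_duplicated_sample_has_identical_coordinates():
    rng = np.random.default_rng(3)
    g = rng.integers(0, 3, size=(200, 4)).astype(np.int8)
    g = np.hstack([g, g[:, :1]])  # duplicate the first sample
    t = make_table([{"pos": i + 1, "genotypes": g[i].tolist()} for i in range(200)],
                   ["s1", "s2", "s3", "s4", "s1b"])
    vecs, _ = pca(t, k=3)
    assert np.allclose(vecs[0], vecs[4], atol=1e-8) or np.allclose(vecs[0], -vecs[4], atol=1e-8)


def test_pca_matches_bruteforce_svd_and_trace():
    t, _ = _balding_nichols_table(7, n_sites=800, n_per_pop=10)
    vecs, vals = pca(t, k=5)
    assert np.all(vals >= -1e-9)
    # oracle: SVD of the scaled matrix gives the same spectrum
    from sweepherd.vcfio import MISSING
    g = t.genotypes.astype(float)
    p = g.mean(axis=1) / 2
    keep = (p > 0) & (p < 1)
    x = (g[keep] - 2 * p[keep, None]) / np.sqrt(2 * p[keep] * (1 - p[keep]))[:, None]
    s = np.linalg.svd(x, compute_uv=False)
    expected = (s ** 2 / x.shape[0])[:5]
    assert np.allclose(vals, expected, atol=1e-8)
    # Patterson scaling: GRM trace is close to the sample count
    grm_trace = (x.T @ x / x.shape[0]).trace()
    assert grm_trace == pytest.approx(t.n_samples, rel=0.2)


def test_pca_monomorphic_only_errors():
    t = make_table([{"pos": 1, "genotypes": [0, 0, 0]}], ["a", "b", "c"])
    with pytest.raises(ValueError):
        pca(t)


# ---------------------------------------------------------------------------
# LD


def test_ld_r2_identical_and_orthogonal_vectors():
    t = make_table([
        {"pos": 100, "genotypes": [0, 2, 0, 2]},
        {"pos": 200, "genotypes": [0, 2, 0, 2]},   # identical -> 1
        {"pos": 300, "genotypes": [0, 0, 2, 2]},   # balanced orthogonal -> 0
    ], list("wxyz"))
    ld = ld_r2(t)
    by = {(r.pos_a, r.pos_b): r.r2 for r in ld.pairs.itertuples()}
    assert by[(100, 200)] == pytest.approx(1.0)
    assert by[(100, 300)] == pytest.approx(0.0, abs=1e-12)


def test_ld_r2_invariant_to_allele_relabeling():
    rng = np.random.default_rng(5)
    g = rng.integers(0, 3, size=(10, 20)).astype(np.int8)
    t1 = make_table([{"pos": 10 * (i + 1), "genotypes": g[i].tolist()} for i in range(10)],
                    [f"s{i}" for i in range(20)])
    g2 = (2 - g).astype(np.int8)
    t2 = make_table([{"pos": 10 * (i + 1), "genotypes": g2[i].tolist()} for i in range(10)],
                    [f"s{i}" for i in range(20)])
    p1 = ld_r2(t1).pairs
    p2 = ld_r2(t2).pairs
    assert np.allclose(p1["r2"], p2["r2"], atol=1e-12)


def test_ld_r2_zero_variance_pair_skipped():
    t = make_table([
        {"pos": 1, "genotypes": [1, 1, 1, 1]},
        {"pos": 2, "genotypes": [0, 1, 2, 1]},
    ], list("abcd"))
    ld = ld_r2(t)
    assert ld.pairs.empty and ld.n_skipped == 1


def test_ld_decay_bins_and_flat_under_no_linkage():
    rng = np.random.default_rng(12)
    n_samples, n_sites = 50, 300
    p = rng.uniform(0.2, 0.8, size=n_sites)
    g = rng.binomial(2, p[:, None], size=(n_sites, n_samples)).astype(np.int8)
    t = make_table([{"pos": 100 * (i + 1), "genotypes": g[i].tolist()} for i in range(n_sites)],
                   [f"s{i}" for i in range(n_samples)])
    ld = ld_r2(t, max_bp=5000)
    curve = ld_decay(ld, 1000)
    assert (curve["mean_r2"] >= 0).all() and (curve["mean_r2"] <= 1).all()
    # independent sites: E[r^2] ~ 1/n
    assert curve["mean_r2"].mean() == pytest.approx(1 / n_samples, abs=0.02)


def test_ld_thin_collapses_perfectly_correlated_window():
    base = [0, 2, 1, 0, 2, 1, 0, 2]
    t = make_table([{"pos": 10 * (i + 1), "genotypes": base} for i in range(10)],
                   [f"s{i}" for i in range(8)])
    out = ld_thin(t, window=50, step=5, r2_max=0.5)
    assert out.n_sites == 1 and out.pos[0] == 10


def test_ld_thin_identity_when_uncorrelated():
    rng = np.random.default_rng(21)
    g = rng.binomial(2, rng.uniform(0.3, 0.7, size=30)[:, None], size=(30, 100)).astype(np.int8)
    t = make_table([{"pos": 10 * (i + 1), "genotypes": g[i].tolist()} for i in range(30)],
                   [f"s{i}" for i in range(100)])
    out = ld_thin(t, r2_max=0.5)
    assert out.n_sites == 30  # independent sites at n=100 never reach r2 0.5
    # survivors respect the cap within any window
    from sweepherd.popstruct import _window_r2_matrix
    sub = out.genotypes.astype(float)
    r2m = _window_r2_matrix(sub)
    iu = np.triu_indices(out.n_sites, 1)
    assert np.nanmax(r2m[iu]) <= 0.5


# ---------------------------------------------------------------------------
# pairwise population FST


def test_fst_resampled_halves_near_zero():
    rng = np.random.default_rng(9)
    n_sites = 5000
    p = rng.uniform(0.1, 0.9, size=n_sites)
    g = rng.binomial(2, p[:, None], size=(n_sites, 40)).astype(np.int8)
    samples = [f"s{i}" for i in range(40)]
    pm = PopulationMap({s: ("L" if i < 20 else "R") for i, s in enumerate(samples)})
    t = make_table([{"pos": i + 1, "genotypes": g[i].tolist()} for i in range(n_sites)], samples)
    mat = pairwise_population_fst(t, pm)
    assert abs(mat.loc["L", "R"]) < 0.01
    assert mat.loc["L", "L"] == 0.0
    assert mat.loc["L", "R"] == mat.loc["R", "L"]


def test_fst_fixed_difference_is_one():
    pm = PopulationMap({"a": "P", "b": "P", "c": "Q", "d": "Q"})
    t = make_table([{"pos": i, "genotypes": [0, 0, 2, 2]} for i in (1, 2, 3)], list("abcd"))
    mat = pairwise_population_fst(t, pm)
    assert mat.loc["P", "Q"] == pytest.approx(1.0)
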