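"""Hypergeometric over-representation of a candidate gene set against a
genome background, with Benjamini-Hochberg FDR control.

The p-value of a term with K background genes is the upper tail
P[X >= k], X ~ Hypergeom(N, K, n), for k candidate members among n
candidates drawn from N background genes.
"""

from sweepherd import hypergeom_enrich

# toy background of 30 genes; term GO:A is concentrated in the candidates
term_map = {}
for i in range(30):
    gene = f"g{i:02d}"
    term_map[gene] = [("GO:B", "housekeeping")]
    if i < 6:
        term_map[gene].append(("GO:A", "fiber development"))

candidates = ["g00", "g01", "g02", "g03", "g04", "g10"]
rows = hypergeom_enrich(candidates, term_map)

print(f"{len(candidates)} candidates vs {rows[0].N} background genes")
for r in rows:
    flag = " *" if r.q <= 0.05 else ""
    print(f"{r.term_id:6s} {r.term_name:18s} k={r.k} K={r.K} "
          f"p={r.p:.3g} q={r.q:.3g}{flag}")
print("\n'*' marks terms significant at FDR <= 0.05; five of the six")
print("'fiber development' genes among six candidates is a strong excess.")
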