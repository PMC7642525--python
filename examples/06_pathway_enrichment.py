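"""Hypergeometric pathway enrichment of candidate genes.

For each pathway hit in at least two families, P is the upper-tail
hypergeometric probability of seeing >= m candidate genes in a pathway of
M genes when n candidates are drawn from the N-gene pathway universe;
q-values are Benjamini-Hochberg, and significance requires P < 0.05 and
q < 0.2.
"""

from twinseg.enrich import enrich_families, hypergeom_tail

pathways = {
    "chondrocyte_differentiation": {f"CHD{i}" for i in range(25)},
    "ear_morphogenesis": {f"EAR{i}" for i in range(20)},
    "housekeeping": {f"HK{i}" for i in range(200)},
}
family_candidates = {
    "FAM01": {"EAR1", "EAR5", "HK3"},
    "FAM02": {"EAR2", "CHD1"},
    "FAM03": {"EAR7"},
}

print(f"single call: P = {hypergeom_tail(M=5, m=3, N=50, n=10):.6f} "
      "(3 of 10 candidates landing in a 5-gene pathway out of 50)")

for r in enrich_families(family_candidates, pathways, min_recurrent_families=2):
    print(
        f"{r.pathway:28s} M={r.M:3d} m={r.m} N={r.N} n={r.n} "
        f"P={r.P:.4g} q={r.q:.4g} families={len(r.families_hit)} "
        f"significant={r.significant}"
    )
# The ear-morphogenesis pathway, hit in all three families and enriched in
# the pooled candidate set, comes out with the smallest P.
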