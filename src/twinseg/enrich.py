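"""Hypergeometric pathway enrichment of candidate genes.

The enrichment probability for a pathway is the upper tail of the
hypergeometric distribution,

    P = 1 - sum_{i=0}^{m-1} C(M, i) C(N - M, n - i) / C(N, n),

where M is the number of genes in the pathway, m the number of candidate
genes in the pathway, N the number of genes across all pathways (the union
of the gene sets), and n the number of candidate genes within N. The sum
is evaluated with exact integer combinatorics (no floating cancellation):
the shorter of the lower and upper tails is accumulated and the final
division to a float is correctly rounded.

Pathways are tested only when hit by candidate genes in at least
``min_recurrent_families`` distinct families; Benjamini-Hochberg q-values
are computed over the tested pathways only, and a pathway is significant
when P < 0.05 and q < 0.2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb
from typing import Mapping

logger = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 0.05
DEFAULT_Q_THRESHOLD = 0.2


@dataclass(frozen=True)
class PathwayEnrichmentResult:
    pathway: str
    M: int  # genes in the pathway
    m: int  # candidate genes in the pathway
    N: int  # genes across all pathways
    n: int  # candidate genes within N
    P: float
    q: float
    families_hit: frozenset = frozenset()
    per_family_p: Mapping[str, float] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.P < DEFAULT_P_THRESHOLD and self.q < DEFAULT_Q_THRESHOLD


def hypergeom_tail(M: int, m: int, N: int, n: int) -> float:
    """Upper-tail probability of seeing >= m pathway genes among n draws.

    Exact: the numerator is an integer sum of C(M, i) * C(N - M, n - i)
    terms (shorter tail, complemented when cheaper) divided by C(N, n).
    """
    if not (0 <= M <= N):
        raise ValueError(f"require 0 <= M <= N, got M={M}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"require 0 <= n <= N, got n={n}, N={N}")
    if not (0 <= m <= min(M, n)):
        raise ValueError(f"require 0 <= m <= min(M, n), got m={m}, M={M}, n={n}")
    if m == 0:
        return 1.0
    denom = comb(N, n)
    hi = min(M, n)
    if hi - m + 1 <= m:  # upper tail is shorter
        num = sum(comb(M, i) * comb(N - M, n - i) for i in range(m, hi + 1))
        return num / denom
    lower = sum(comb(M, i) * comb(N - M, n - i) for i in range(m))
    return (denom - lower) / denom


def bh_qvalues(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted values (monotone step-up)."""
    k = len(pvalues)
    order = sorted(range(k), key=lambda i: pvalues[i])
    q = [0.0] * k
    running_min = 1.0
    for rank_from_top in range(k, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, pvalues[i] * k / rank_from_top)
        q[i] = running_min
    return q


def enrich_families(
    family_candidates: Mapping[str, set],
    pathways: Mapping[str, set],
    min_recurrent_families: int = 2,
) -> list[PathwayEnrichmentResult]:
    """Score pathways recurrently hit across families.

    ``family_candidates`` maps family ID to that family's candidate gene
    set. The gene universe N is the union of all pathway genes; candidate
    genes outside every pathway are excluded from n (and logged). A pathway
    is *hit* by a family when it contains at least one of the family's
    candidate genes; pathways hit in >= ``min_recurrent_families`` families
    are tested with the pooled (union) candidate set. Per-family upper-tail
    probabilities are emitted alongside for transparency.
    """
    if not pathways:
        raise ValueError("empty pathway collection")
    universe: set = set().union(*pathways.values())
    N = len(universe)
    pooled_all = set().union(*family_candidates.values()) if family_candidates else set()
    pooled = pooled_all & universe
    outside = pooled_all - universe
    if outside:
        logger.info(
            "%d candidate genes absent from every pathway were excluded from n",
            len(outside),
        )
    n = len(pooled)
    per_family_in_universe = {
        fam: genes & universe for fam, genes in family_candidates.items()
    }

    tested: list[tuple[str, int, int, frozenset, dict]] = []
    for pathway, genes in sorted(pathways.items()):
        hit_families = frozenset(
            fam for fam, cand in per_family_in_universe.items() if cand & genes
        )
        if len(hit_families) < min_recurrent_families:
            continue
        M = len(genes)
        m = len(pooled & genes)
        per_family_p = {
            fam: hypergeom_tail(M, len(cand & genes), N, len(cand))
            for fam, cand in sorted(per_family_in_universe.items())
            if fam in hit_families
        }
        tested.append((pathway, M, m, hit_families, per_family_p))

    pvalues = [hypergeom_tail(M, m, N, n) for _, M, m, _, _ in tested]
    qvalues = bh_qvalues(pvalues)
    results = [
        PathwayEnrichmentResult(
            pathway=pathway,
            M=M,
            m=m,
            N=N,
            n=n,
            P=p,
            q=q,
            families_hit=hit_families,
            per_family_p=per_family_p,
        )
        for (pathway, M, m, hit_families, per_family_p), p, q in zip(
            tested, pvalues, qvalues
        )
    ]
    results.sort(key=lambda r: (r.P, r.pathway))
    return results


def enrichment_table(results: list[PathwayEnrichmentResult]):
    import pandas as pd

    return pd.DataFrame(
        {
            "pathway": [r.pathway for r in results],
            "M": [r.M for r in results],
            "m": [r.m for r in results],
            "N": [r.N for r in results],
            "n": [r.n for r in results],
            "P": [r.P for r in results],
            "q": [r.q for r in results],
            "families_hit": ["|".join(sorted(r.families_hit)) for r in results],
            "significant": [r.significant for r in results],
        }
    )
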