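"""Cross-family recurrence of candidate variants, genes and CNV-hit genes.

A mutation shared by unrelated families is unlikely to be a private
artefact and is prioritized as potentially pathogenic. Recurrence is
counted over *distinct families* (two twins of one pair never count twice):

* variant level — the same normalized key (chrom, pos, ref, alt) observed
  as a candidate in at least ``min_families`` families;
* gene level — any candidate event in the gene in at least ``min_families``
  families, possibly through different variants;
* CNV level — a gene whose interval is overlapped (>= 1 base) by a called
  gain/loss segment in at least ``min_families`` families.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from twinseg.segfilter import CandidateEvent, VariantKey


@dataclass(frozen=True)
class RecurrentVariant:
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    hgvs_c: str
    hgvs_p: str
    families: frozenset

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def n_families(self) -> int:
        return len(self.families)


@dataclass(frozen=True)
class RecurrentGene:
    gene: str
    families: frozenset
    variant_keys: tuple

    @property
    def n_families(self) -> int:
        return len(self.families)

    @property
    def n_variants(self) -> int:
        return len(self.variant_keys)


@dataclass(frozen=True)
class RecurrentCnvGene:
    gene: str
    carriers: tuple  # subject IDs, as reported
    families: frozenset
    direction: str  # gain | loss | mixed

    @property
    def n_families(self) -> int:
        return len(self.families)


def recurrent_variants(
    events: Iterable[CandidateEvent], min_families: int = 2
) -> list[RecurrentVariant]:
    """Variants carried as candidates in at least ``min_families`` families."""
    by_key: dict[VariantKey, list[CandidateEvent]] = {}
    for e in events:
        by_key.setdefault(e.key, []).append(e)
    out = []
    for key, group in by_key.items():
        families = frozenset(e.family_id for e in group)
        if len(families) >= min_families:
            first = group[0]
            out.append(
                RecurrentVariant(
                    gene=first.gene,
                    chrom=key[0],
                    pos=key[1],
                    ref=key[2],
                    alt=key[3],
                    hgvs_c=first.hgvs_c,
                    hgvs_p=first.hgvs_p,
                    families=families,
                )
            )
    out.sort(key=lambda r: (-r.n_families, r.gene, r.key))
    return out


def recurrent_genes(
    events: Iterable[CandidateEvent], min_families: int = 2
) -> list[RecurrentGene]:
    """Genes hit by candidate events in at least ``min_families`` families.

    A gene can recur through *different* variants in different families;
    the distinct variant keys are reported alongside.
    """
    by_gene: dict[str, list[CandidateEvent]] = {}
    for e in events:
        by_gene.setdefault(e.gene, []).append(e)
    out = []
    for gene, group in by_gene.items():
        families = frozenset(e.family_id for e in group)
        if len(families) >= min_families:
            keys = tuple(sorted({e.key for e in group}))
            out.append(RecurrentGene(gene=gene, families=families, variant_keys=keys))
    out.sort(key=lambda r: (-r.n_families, r.gene))
    return out


def recurrent_cnv_genes(
    segments: Iterable,
    gene_intervals: pd.DataFrame,
    subject_to_family: Mapping[str, str],
    min_families: int = 2,
) -> list[RecurrentCnvGene]:
    """Genes overlapped by gain/loss CNV segments in >= min_families families.

    ``segments`` are records with ``subject, chrom, start, end, call``
    attributes (e.g. :class:`twinseg.cnvcall.CnvSegment`); neutral segments
    are ignored. ``gene_intervals`` has columns gene, chrom, start, end
    (1-based inclusive). Overlap by a single base counts as a hit.
    """
    hits: dict[str, dict] = {}
    intervals = list(gene_intervals[["gene", "chrom", "start", "end"]].itertuples(index=False))
    for seg in segments:
        if seg.call not in ("gain", "loss"):
            continue
        for gene, chrom, start, end in intervals:
            if str(chrom) != str(seg.chrom):
                continue
            if start <= seg.end and end >= seg.start:
                entry = hits.setdefault(
                    gene, {"carriers": set(), "families": set(), "calls": set()}
                )
                entry["carriers"].add(seg.subject)
                entry["families"].add(subject_to_family[seg.subject])
                entry["calls"].add(seg.call)
    out = []
    for gene, entry in hits.items():
        if len(entry["families"]) < min_families:
            continue
        direction = (
            entry["calls"].pop() if len(entry["calls"]) == 1 else "mixed"
        )
        out.append(
            RecurrentCnvGene(
                gene=gene,
                carriers=tuple(sorted(entry["carriers"])),
                families=frozenset(entry["families"]),
                direction=direction,
            )
        )
    out.sort(key=lambda r: (-r.n_families, -len(r.carriers), r.gene))
    return out


def variant_report(results: list[RecurrentVariant]) -> pd.DataFrame:
    """Report mirroring a gene x family table of HGVS labels."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "chrom": [r.chrom for r in results],
            "pos": [r.pos for r in results],
            "ref": [r.ref for r in results],
            "alt": [r.alt for r in results],
            "hgvs_c": [r.hgvs_c for r in results],
            "hgvs_p": [r.hgvs_p for r in results],
            "families": ["|".join(sorted(r.families)) for r in results],
            "n_families": [r.n_families for r in results],
        }
    )


def cnv_gene_report(results: list[RecurrentCnvGene]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "carriers": ["|".join(r.carriers) for r in results],
            "n_families": [r.n_families for r in results],
            "direction": [r.direction for r in results],
        }
    )
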