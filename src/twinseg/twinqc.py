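"""Zygosity and coverage QC.

Monozygosity is checked by genotype concordance between the two twins:
the fraction of sites at which both twins carry the same genotype category
(hom_ref / het / hom_alt), over sites where both genotypes are non-missing
and pass the depth and genotype-quality thresholds. Monozygotic co-twins
are expected to be concordant at essentially all sites (the residual
discordance being somatic mosaicism plus genotyping error).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from twinseg.vario import QuartetFamily

#: Concordance at or above which a twin pair is reported monozygotic.
#: A conventional QC default, deliberately below the ~0.999 expected for
#: true monozygotic pairs and far above the ~0.5-0.7 of dizygotic pairs.
DEFAULT_MZ_THRESHOLD = 0.99


@dataclass(frozen=True)
class ConcordanceReport:
    family_id: str
    n_sites_compared: int
    n_concordant: int

    @property
    def concordance(self) -> float:
        """Fraction concordant; NaN when no sites were comparable."""
        if self.n_sites_compared == 0:
            return math.nan
        return self.n_concordant / self.n_sites_compared

    def is_monozygotic(self, threshold: float = DEFAULT_MZ_THRESHOLD) -> bool:
        if self.n_sites_compared == 0:
            raise ValueError(
                f"family {self.family_id}: zero comparable sites, "
                "concordance undefined"
            )
        return self.concordance >= threshold


def twin_concordance(
    calls: pd.DataFrame,
    family: QuartetFamily,
    min_gq: int = 20,
    min_depth: int = 8,
) -> ConcordanceReport:
    """Genotype concordance between the proband and the co-twin.

    Sites enter the denominator only when both twins have a non-missing
    genotype with ``gq >= min_gq`` and ``depth >= min_depth``; the
    comparison is symmetric in the two twins.
    """
    for role in ("proband", "cotwin"):
        sample = family.roles[role]
        if sample not in set(calls["sample"]):
            raise ValueError(f"sample {sample!r} (role {role!r}) absent from calls")
    usable = calls[
        (calls["gt"] != "missing")
        & (calls["gq"] >= min_gq)
        & (calls["depth"] >= min_depth)
    ]
    key_cols = ["chrom", "pos", "ref", "alt"]
    twins = usable[usable["sample"].isin([family.proband, family.cotwin])]
    wide = twins.pivot_table(
        index=key_cols, columns="sample", values="gt", aggfunc="first"
    )
    for sample in (family.proband, family.cotwin):
        if sample not in wide.columns:
            wide[sample] = None
    wide = wide.dropna(subset=[family.proband, family.cotwin])
    n = len(wide)
    concordant = int((wide[family.proband] == wide[family.cotwin]).sum())
    return ConcordanceReport(
        family_id=family.family_id, n_sites_compared=n, n_concordant=concordant
    )


def coverage_summary(
    depth_table: pd.DataFrame, min_depth: int = 20
) -> tuple[float, float]:
    """Mean target depth and fraction of targets covered at >= min_depth."""
    if len(depth_table) == 0:
        raise ValueError("depth table is empty")
    depths = depth_table["depth"].to_numpy(dtype=float)
    return float(depths.mean()), float((depths >= min_depth).mean())


def concordance_table(reports: list[ConcordanceReport]) -> pd.DataFrame:
    """Tab-separated-ready QC report across families."""
    return pd.DataFrame(
        {
            "family_id": [r.family_id for r in reports],
            "n_sites_compared": [r.n_sites_compared for r in reports],
            "n_concordant": [r.n_concordant for r in reports],
            "concordance": [r.concordance for r in reports],
        }
    )
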