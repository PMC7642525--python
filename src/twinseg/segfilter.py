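"""Segregation and annotation filtering of post-twinning de novo candidates.

The core procedure of the quartet design. A variant is a post-twinning de
novo candidate when the affected twin carries the alternate allele with
adequate read support while the unaffected co-twin and both parents are
confidently homozygous reference (genotype hom_ref *and* alt-allele read
fraction at or below ``max_carrier_alt_fraction``). A variant carried by
both twins but absent in the parents arose before the twinning split — a
conventional germline de novo mutation — and cannot explain the discordant
phenotype; it is classified separately as pre-twinning.

Surviving keys then pass three annotation filters:

1. protein-altering functional classes only (frameshift, coding indels,
   missense, stopgain, intron-exon boundary);
2. exclusion of common variants — frequency strictly above ``maf_threshold``
   (default 10%) in at least one of the five population databases; a
   frequency absent from a database never triggers exclusion;
3. exclusion of synonymous and intronic classes.

Every retained event carries full filter provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from twinseg.vario import (
    FUNCTIONAL_CLASSES,
    AnnotatedVariant,
    QuartetFamily,
    read_annotation_table,
    read_family_vcf,
)

logger = logging.getLogger(__name__)

VariantKey = tuple[str, int, str, str]

CARRIER_ROLES = ("cotwin", "father", "mother")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for segregation and annotation filtering.

    The MAF threshold and the class sets follow the published criteria; the
    read-evidence thresholds (minimum proband depths, maximum alt-allele
    fraction tolerated in a homozygous-reference carrier) are artifact
    defaults chosen to suppress allele-dropout false positives.
    """

    maf_threshold: float = 0.10
    protein_altering_classes: frozenset = frozenset(
        {"frameshift", "nonframeshift_indel", "missense", "stopgain", "splice_boundary"}
    )
    excluded_classes: frozenset = frozenset({"synonymous", "intronic"})
    min_proband_alt_depth: int = 4
    min_proband_depth: int = 10
    max_carrier_alt_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_threshold <= 1.0):
            raise ValueError(f"maf_threshold must be in (0, 1], got {self.maf_threshold}")
        overlap = self.protein_altering_classes & self.excluded_classes
        if overlap:
            raise ValueError(f"class sets overlap: {sorted(overlap)}")
        unknown = (self.protein_altering_classes | self.excluded_classes) - FUNCTIONAL_CLASSES
        if unknown:
            raise ValueError(f"unknown functional classes: {sorted(unknown)}")
        if not (0.0 <= self.max_carrier_alt_fraction < 1.0):
            raise ValueError("max_carrier_alt_fraction must be in [0, 1)")


@dataclass(frozen=True)
class FilterStep:
    name: str
    passed: bool
    detail: str = ""


@dataclass(frozen=True)
class CandidateEvent:
    """A variant that survived every configured filter in one family."""

    family_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    functional_class: str
    hgvs_c: str = ""
    hgvs_p: str = ""
    genotypes: Mapping[str, dict] = field(default_factory=dict)
    provenance: tuple[FilterStep, ...] = ()

    def __post_init__(self) -> None:
        failed = [s.name for s in self.provenance if not s.passed]
        if failed:
            raise ValueError(
                f"CandidateEvent requires all filters passed; failed: {failed}"
            )

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class RejectedVariant:
    """A segregating variant removed by an annotation filter, with provenance."""

    family_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    functional_class: str
    provenance: tuple[FilterStep, ...] = ()

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def failed_filters(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.provenance if not s.passed)


@dataclass(frozen=True)
class SegregationResult:
    """Keys split by when the mutation arose relative to the twinning split."""

    post_twinning: frozenset
    pre_twinning: frozenset
    evidence: Mapping[VariantKey, Mapping[str, dict]] = field(default_factory=dict)


def _role_frames(calls: pd.DataFrame, family: QuartetFamily) -> pd.DataFrame:
    present = set(calls["sample"])
    for role, sample in family.roles.items():
        if sample not in present:
            raise ValueError(
                f"family {family.family_id}: sample {sample!r} (role {role!r}) "
                "absent from calls"
            )
    sample_role = {s: r for r, s in family.roles.items()}
    fam_calls = calls[calls["sample"].isin(sample_role)].copy()
    fam_calls["role"] = fam_calls["sample"].map(sample_role)
    wide = fam_calls.pivot_table(
        index=["chrom", "pos", "ref", "alt"],
        columns="role",
        values=["gt", "depth", "alt_depth"],
        aggfunc="first",
    )
    return wide


def segregate_family(
    calls: pd.DataFrame, family: QuartetFamily, config: FilterConfig | None = None
) -> SegregationResult:
    """Classify family variants into post- and pre-twinning de novo keys.

    Post-twinning: proband carries with sufficient read evidence, co-twin
    and both parents are confident hom_ref. Pre-twinning: both twins carry,
    both parents are confident hom_ref. Sites with a missing genotype in any
    required non-proband member are excluded (conservative).
    """
    config = config or FilterConfig()
    wide = _role_frames(calls, family)
    roles = ("proband", "cotwin", "father", "mother")

    def col(value: str, role: str) -> pd.Series:
        if (value, role) in wide.columns:
            return wide[(value, role)]
        return pd.Series([None] * len(wide), index=wide.index)

    gt = {r: col("gt", r) for r in roles}
    depth = {r: col("depth", r).astype(float) for r in roles}
    alt_depth = {r: col("alt_depth", r).astype(float) for r in roles}

    carries = {r: gt[r].isin(["het", "hom_alt"]) for r in roles}
    proband_ok = (
        carries["proband"]
        & (alt_depth["proband"] >= config.min_proband_alt_depth)
        & (depth["proband"] >= config.min_proband_depth)
    )

    def confident_hom_ref(role: str) -> pd.Series:
        frac = alt_depth[role].where(depth[role] > 0, 0) / depth[role].where(
            depth[role] > 0, 1
        )
        return (gt[role] == "hom_ref") & (frac <= config.max_carrier_alt_fraction)

    carriers_clear = (
        confident_hom_ref("cotwin")
        & confident_hom_ref("father")
        & confident_hom_ref("mother")
    )
    parents_clear = confident_hom_ref("father") & confident_hom_ref("mother")

    post = wide.index[proband_ok & carriers_clear]
    pre = wide.index[proband_ok & carries["cotwin"].fillna(False) & parents_clear]

    evidence: dict[VariantKey, dict[str, dict]] = {}
    for key in list(post) + list(pre):
        evidence[key] = {
            r: {
                "gt": gt[r].get(key),
                "depth": None if pd.isna(depth[r].get(key)) else int(depth[r].get(key)),
                "alt_depth": None
                if pd.isna(alt_depth[r].get(key))
                else int(alt_depth[r].get(key)),
            }
            for r in roles
        }
    return SegregationResult(
        post_twinning=frozenset(post), pre_twinning=frozenset(pre), evidence=evidence
    )


def segregate_de_novo(
    calls: pd.DataFrame, family: QuartetFamily, config: FilterConfig | None = None
) -> frozenset:
    """Post-twinning de novo candidate keys for one quartet."""
    return segregate_family(calls, family, config).post_twinning


def annotation_provenance(
    ann: AnnotatedVariant, config: FilterConfig
) -> tuple[bool, tuple[FilterStep, ...]]:
    """Evaluate the three annotation criteria, recording each outcome."""
    in_protein = ann.functional_class in config.protein_altering_classes
    not_excluded = ann.functional_class not in config.excluded_classes
    max_maf = ann.max_present_maf()
    common = max_maf is not None and max_maf > config.maf_threshold
    steps = (
        FilterStep(
            "protein_altering_class",
            in_protein,
            f"class={ann.functional_class}",
        ),
        FilterStep(
            "excluded_class",
            not_excluded,
            f"class={ann.functional_class}",
        ),
        FilterStep(
            "population_maf",
            not common,
            "all databases absent" if max_maf is None else f"max MAF={max_maf:g}",
        ),
    )
    return in_protein and not_excluded and not common, steps


def apply_annotation_filters(
    keys: Iterable[VariantKey],
    annotations: Iterable[AnnotatedVariant],
    config: FilterConfig | None = None,
    family_id: str = "",
    evidence: Mapping[VariantKey, Mapping[str, dict]] | None = None,
    with_rejected: bool = False,
):
    """Apply the class and frequency criteria to segregating keys.

    Keys with no annotation row are dropped (count logged). Returns the
    retained :class:`CandidateEvent` list; with ``with_rejected=True``
    also returns the :class:`RejectedVariant` list whose provenance shows
    which criterion failed.
    """
    config = config or FilterConfig()
    ann_by_key = {a.key: a for a in annotations}
    evidence = evidence or {}
    passed: list[CandidateEvent] = []
    rejected: list[RejectedVariant] = []
    n_unannotated = 0
    seg_steps = (
        FilterStep("segregation", True, "proband-only, carriers hom_ref"),
    )
    for key in sorted(keys):
        ann = ann_by_key.get(key)
        if ann is None:
            n_unannotated += 1
            continue
        ok, steps = annotation_provenance(ann, config)
        if ok:
            passed.append(
                CandidateEvent(
                    family_id=family_id,
                    chrom=key[0],
                    pos=key[1],
                    ref=key[2],
                    alt=key[3],
                    gene=ann.gene,
                    functional_class=ann.functional_class,
                    hgvs_c=ann.hgvs_c,
                    hgvs_p=ann.hgvs_p,
                    genotypes=dict(evidence.get(key, {})),
                    provenance=seg_steps + steps,
                )
            )
        else:
            rejected.append(
                RejectedVariant(
                    family_id=family_id,
                    chrom=key[0],
                    pos=key[1],
                    ref=key[2],
                    alt=key[3],
                    gene=ann.gene,
                    functional_class=ann.functional_class,
                    provenance=seg_steps + steps,
                )
            )
    if n_unannotated:
        logger.warning(
            "family %s: %d segregating keys had no annotation row and were dropped",
            family_id or "?",
            n_unannotated,
        )
    if with_rejected:
        return passed, rejected
    return passed


def run_family(
    vcf_path: str | Path,
    annotation_path: str | Path,
    family: QuartetFamily,
    config: FilterConfig | None = None,
) -> list[CandidateEvent]:
    """Full per-family stage: read, segregate, annotate, filter."""
    config = config or FilterConfig()
    calls = read_family_vcf(vcf_path, family)
    if calls.empty:
        return []
    seg = segregate_family(calls, family, config)
    annotations = read_annotation_table(annotation_path)
    events = apply_annotation_filters(
        seg.post_twinning,
        annotations,
        config,
        family_id=family.family_id,
        evidence=seg.evidence,
    )
    logger.info(
        "family %s: %d post-twinning keys, %d pre-twinning keys, %d candidates",
        family.family_id,
        len(seg.post_twinning),
        len(seg.pre_twinning),
        len(events),
    )
    return events


def events_table(events: Iterable[CandidateEvent]) -> pd.DataFrame:
    """Tab-separated-ready candidate table, one provenance column per filter."""
    rows = []
    for e in events:
        row = {
            "family_id": e.family_id,
            "chrom": e.chrom,
            "pos": e.pos,
            "ref": e.ref,
            "alt": e.alt,
            "gene": e.gene,
            "functional_class": e.functional_class,
            "hgvs_c": e.hgvs_c,
            "hgvs_p": e.hgvs_p,
        }
        for role, info in e.genotypes.items():
            row[f"{role}_gt"] = info.get("gt")
            row[f"{role}_ad"] = (
                f"{info.get('alt_depth')}/{info.get('depth')}"
                if info.get("depth") is not None
                else ""
            )
        for step in e.provenance:
            row[f"filter_{step.name}"] = "pass" if step.passed else "fail"
        rows.append(row)
    return pd.DataFrame(rows)
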