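"""Readers and writers for the formats the pipeline touches.

Coordinates are 1-based inclusive throughout (VCF convention). Chromosome
names are normalized by stripping a leading ``chr``. Variant identity is the
tuple ``(chrom, pos, ref, alt)`` after multi-allelic splitting and minimal
representation (shared suffix then shared prefix trimmed, position advanced
over the trimmed prefix) so that recurrence matching across families is not
defeated by representation differences.

Genotype tables are plain :class:`pandas.DataFrame` objects with one row per
sample per ALT allele and the columns ``sample, chrom, pos, ref, alt, gt,
depth, alt_depth, gq``; ``gt`` is one of ``hom_ref / het / hom_alt /
missing`` (the count of the split-out ALT allele in the diploid genotype).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

#: Closed functional-class vocabulary used by the annotation filters.
FUNCTIONAL_CLASSES = frozenset(
    {
        "missense",
        "stopgain",
        "frameshift",
        "nonframeshift_indel",
        "splice_boundary",
        "synonymous",
        "intronic",
    }
)

#: The five population-frequency columns checked by the MAF filter
#: (1000 Genomes, HapMap CHB, NHLBI ESP, dbSNP v.144, ExAC).
MAF_COLUMNS = ("maf_1000g", "maf_hapmap_chb", "maf_esp", "maf_dbsnp", "maf_exac")

#: Optional in-silico prediction columns carried through when present.
PREDICTION_COLUMNS = ("sift", "polyphen2", "mutation_taster", "cadd")

GT_CATEGORIES = ("hom_ref", "het", "hom_alt", "missing")

CALL_COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "gt", "depth", "alt_depth", "gq"]

#: ANNOVAR-style functional class strings mapped onto the closed vocabulary.
DEFAULT_CLASS_SYNONYMS: Mapping[str, str] = {
    "missense": "missense",
    "nonsynonymous SNV": "missense",
    "missense SNV": "missense",
    "stopgain": "stopgain",
    "stopgain SNV": "stopgain",
    "nonsense": "stopgain",
    "frameshift": "frameshift",
    "frameshift insertion": "frameshift",
    "frameshift deletion": "frameshift",
    "frameshift substitution": "frameshift",
    "nonframeshift_indel": "nonframeshift_indel",
    "nonframeshift insertion": "nonframeshift_indel",
    "nonframeshift deletion": "nonframeshift_indel",
    "nonframeshift substitution": "nonframeshift_indel",
    "splice_boundary": "splice_boundary",
    "splicing": "splice_boundary",
    "splice-site": "splice_boundary",
    "intron-exon boundary": "splice_boundary",
    "synonymous": "synonymous",
    "synonymous SNV": "synonymous",
    "intronic": "intronic",
    "intron": "intronic",
}


class VarioError(ValueError):
    """Raised for malformed or incomplete input files."""


@dataclass(frozen=True)
class QuartetFamily:
    """The unit of segregation analysis: affected twin, co-twin, two parents."""

    family_id: str
    proband: str
    cotwin: str
    father: str
    mother: str

    def __post_init__(self) -> None:
        members = (self.proband, self.cotwin, self.father, self.mother)
        if len(set(members)) != 4:
            raise VarioError(
                f"family {self.family_id}: the four member sample IDs must be "
                f"distinct, got {members}"
            )

    @property
    def roles(self) -> dict[str, str]:
        """Mapping of role name to sample ID."""
        return {
            "proband": self.proband,
            "cotwin": self.cotwin,
            "father": self.father,
            "mother": self.mother,
        }

    @property
    def members(self) -> tuple[str, str, str, str]:
        return (self.proband, self.cotwin, self.father, self.mother)


@dataclass(frozen=True)
class AnnotatedVariant:
    """One normalized variant joined to its functional annotation.

    ``maf`` holds the five population frequencies (``None`` = absent from the
    database, which is *not* the same as frequency zero for filtering
    purposes); ``predictions`` holds optional in-silico labels.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    functional_class: str
    hgvs_c: str = ""
    hgvs_p: str = ""
    maf: dict = field(default_factory=dict)
    predictions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise VarioError(
                f"functional_class {self.functional_class!r} not in vocabulary"
            )
        for name, value in self.maf.items():
            if value is not None and not (0.0 <= value <= 1.0):
                raise VarioError(f"MAF {name}={value} outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def max_present_maf(self) -> float | None:
        present = [v for v in self.maf.values() if v is not None]
        return max(present) if present else None


def normalize_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def normalize_variant(chrom: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
    """Reduce a variant to its minimal left-aligned representation.

    Operates on the allele strings alone (no reference genome): the shared
    suffix is trimmed first, then the shared prefix is trimmed while
    advancing the position, keeping at least one base on each allele.
    """
    if ref == alt:
        raise VarioError(f"ref and alt identical at {chrom}:{pos} ({ref})")
    if pos < 1:
        raise VarioError(f"position must be >= 1, got {pos}")
    chrom = normalize_chrom(chrom)
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return chrom, pos, ref, alt


def _gt_category(alleles: list[int], alt_index: int) -> str:
    if any(a < 0 for a in alleles):
        return "missing"
    copies = sum(1 for a in alleles if a == alt_index)
    return ("hom_ref", "het", "hom_alt")[copies]


def read_family_vcf(path: str | Path, family: QuartetFamily) -> pd.DataFrame:
    """Read a four-sample family VCF into a genotype-call table.

    Multi-allelic records are split into one biallelic record per ALT allele
    with per-allele depths taken from the AD field. Records whose FILTER is
    neither PASS nor ``.`` are dropped (the count is logged). Variant keys
    are normalized on the way in.
    """
    vcf = VCF(str(path))
    present = set(vcf.samples)
    for role, sample in family.roles.items():
        if sample not in present:
            raise VarioError(
                f"sample {sample!r} (role {role!r}) of family "
                f"{family.family_id} is missing from {path}"
            )
    sample_idx = [vcf.samples.index(s) for s in family.members]

    rows: list[tuple] = []
    n_filtered = 0
    for rec_no, v in enumerate(vcf, start=1):
        try:
            if v.FILTER is not None:  # cyvcf2: None means PASS or '.'
                n_filtered += 1
                continue
            depths = v.format("DP")
            ads = v.format("AD")
            gqs = v.format("GQ")
            genotypes = v.genotypes
            for k, alt in enumerate(v.ALT):
                chrom, pos, ref, nalt = normalize_variant(v.CHROM, v.POS, v.REF, alt)
                for idx, sample in zip(sample_idx, family.members):
                    alleles = list(genotypes[idx][:-1])
                    gt = _gt_category(alleles, k + 1)
                    # htslib encodes absent FORMAT integers as large negatives
                    depth = max(int(depths[idx][0]), 0) if depths is not None else 0
                    alt_depth = max(int(ads[idx][k + 1]), 0) if ads is not None else 0
                    gq = max(int(gqs[idx][0]), 0) if gqs is not None else 0
                    rows.append((sample, chrom, pos, ref, nalt, gt, depth, alt_depth, gq))
        except VarioError:
            raise
        except Exception as exc:  # malformed record content
            raise VarioError(f"{path}: malformed record #{rec_no}: {exc}") from exc
    if n_filtered:
        logger.info("%s: dropped %d non-PASS records", path, n_filtered)
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    if not df.empty and (df["alt_depth"] > df["depth"]).any():
        bad = df[df["alt_depth"] > df["depth"]].iloc[0]
        raise VarioError(
            f"{path}: alt_depth > depth for {bad['sample']} at "
            f"{bad['chrom']}:{bad['pos']}"
        )
    return df


def write_genotype_calls_vcf(
    calls: pd.DataFrame, path: str | Path, samples: list[str] | None = None
) -> None:
    """Write a genotype-call table back out as a biallelic VCF v4.2.

    One record per distinct ``(chrom, pos, ref, alt)``; samples without a
    row at a site are emitted as missing. Inverse of :func:`read_family_vcf`
    for already-normalized biallelic tables.
    """
    if samples is None:
        samples = sorted(calls["sample"].unique())
    def chrom_rank(c: str) -> tuple[int, str]:
        return (0, f"{int(c):03d}") if c.isdigit() else (1, c)

    sites = (
        calls[["chrom", "pos", "ref", "alt"]]
        .drop_duplicates()
        .assign(_rank=lambda d: d["chrom"].map(chrom_rank))
        .sort_values(["_rank", "pos", "ref", "alt"])
        .drop(columns="_rank")
        .reset_index(drop=True)
    )
    chrom_order = {c: chrom_rank(c) for c in sites["chrom"].unique()}
    by_key: dict[tuple, dict[str, tuple]] = {}
    for row in calls.itertuples(index=False):
        by_key.setdefault((row.chrom, row.pos, row.ref, row.alt), {})[row.sample] = row

    gt_string = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "missing": "./."}
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(set(calls["chrom"]), key=lambda c: chrom_order[c]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        fh.write(
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for site in sites.itertuples(index=False):
            key = (site.chrom, site.pos, site.ref, site.alt)
            cells = []
            for sample in samples:
                row = by_key[key].get(sample)
                if row is None:
                    cells.append("./.:.:.:.")
                else:
                    ref_depth = row.depth - row.alt_depth
                    cells.append(
                        f"{gt_string[row.gt]}:{row.depth}:{ref_depth},{row.alt_depth}:{row.gq}"
                    )
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\tPASS\t.\t"
                "GT:DP:AD:GQ\t" + "\t".join(cells) + "\n"
            )


def read_annotation_table(
    path: str | Path, class_synonyms: Mapping[str, str] | None = None
) -> list[AnnotatedVariant]:
    """Read an ANNOVAR-style tab-separated annotation table.

    Empty MAF cells (or ``.``/``NA``) are parsed as absent, never as zero.
    Functional-class strings outside the closed vocabulary are mapped
    through ``class_synonyms``; unmapped values raise.
    """
    synonyms = dict(DEFAULT_CLASS_SYNONYMS if class_synonyms is None else class_synonyms)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["chrom", "pos", "ref", "alt", "gene", "functional_class", *MAF_COLUMNS]
    for col in required:
        if col not in df.columns:
            raise VarioError(f"{path}: required annotation column {col!r} is missing")

    def parse_maf(cell: str) -> float | None:
        cell = cell.strip()
        if cell in ("", ".", "NA", "NaN"):
            return None
        return float(cell)

    out: list[AnnotatedVariant] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        raw_class = getattr(row, "functional_class").strip()
        if raw_class not in synonyms:
            raise VarioError(
                f"{path} line {i}: functional class {raw_class!r} is not in the "
                "vocabulary and has no synonym mapping"
            )
        chrom, pos, ref, alt = normalize_variant(
            row.chrom, int(row.pos), row.ref, row.alt
        )
        maf = {name: parse_maf(getattr(row, name)) for name in MAF_COLUMNS}
        predictions = {
            name: getattr(row, name)
            for name in PREDICTION_COLUMNS
            if name in df.columns and getattr(row, name).strip() not in ("", ".")
        }
        out.append(
            AnnotatedVariant(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                gene=row.gene,
                functional_class=synonyms[raw_class],
                hgvs_c=getattr(row, "hgvs_c", ""),
                hgvs_p=getattr(row, "hgvs_p", ""),
                maf=maf,
                predictions=predictions,
            )
        )
    return out


def write_annotation_table(variants: Iterable[AnnotatedVariant], path: str | Path) -> None:
    """Write annotations in the tab-separated layout read_annotation_table expects."""
    cols = [
        "chrom",
        "pos",
        "ref",
        "alt",
        "gene",
        "functional_class",
        "hgvs_c",
        "hgvs_p",
        *MAF_COLUMNS,
    ]
    with Path(path).open("w") as fh:
        fh.write("\t".join(cols) + "\n")
        for v in variants:
            maf_cells = [
                "" if v.maf.get(name) is None else f"{v.maf[name]:.6g}"
                for name in MAF_COLUMNS
            ]
            fh.write(
                "\t".join(
                    [
                        v.chrom,
                        str(v.pos),
                        v.ref,
                        v.alt,
                        v.gene,
                        v.functional_class,
                        v.hgvs_c,
                        v.hgvs_p,
                        *maf_cells,
                    ]
                )
                + "\n"
            )


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file (set name, description, member genes).

    Duplicate genes within a set are deduplicated; a line with fewer than
    three fields (i.e. an empty set) is rejected with its line number.
    """
    sets: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            genes = {g for g in fields[2:] if g}
            if len(fields) < 3 or not genes:
                raise VarioError(
                    f"{path} line {line_no}: GMT line needs a name, a "
                    "description and at least one gene"
                )
            sets[fields[0]] = genes
    return sets


def read_pedigree(path: str | Path) -> tuple[list[QuartetFamily], dict[str, str]]:
    """Read a PED-with-role file into quartet families.

    Expected columns: family_id, sample, father, mother, sex, phenotype,
    role — role one of proband_twin / cotwin / father / mother. Returns the
    families plus a sample -> family_id mapping.
    """
    role_map = {"proband_twin": "proband", "cotwin": "cotwin", "father": "father", "mother": "mother"}
    per_family: dict[str, dict[str, str]] = {}
    sample_family: dict[str, str] = {}
    with Path(path).open() as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 7:
                raise VarioError(f"{path} line {line_no}: expected 7 columns")
            fam, sample, _father, _mother, _sex, _phen, role = fields[:7]
            if role not in role_map:
                raise VarioError(f"{path} line {line_no}: unknown role {role!r}")
            per_family.setdefault(fam, {})[role_map[role]] = sample
            sample_family[sample] = fam
    families = []
    for fam, roles in per_family.items():
        missing = set(role_map.values()) - set(roles)
        if missing:
            raise VarioError(f"{path}: family {fam} lacks roles {sorted(missing)}")
        families.append(QuartetFamily(family_id=fam, **roles))
    families.sort(key=lambda f: f.family_id)
    return families, sample_family


def write_pedigree(families: Iterable[QuartetFamily], path: str | Path) -> None:
    """Write quartet families as a PED-with-role file."""
    rows = []
    for fam in families:
        rows.append((fam.family_id, fam.father, "0", "0", "1", "1", "father"))
        rows.append((fam.family_id, fam.mother, "0", "0", "2", "1", "mother"))
        rows.append(
            (fam.family_id, fam.proband, fam.father, fam.mother, "0", "2", "proband_twin")
        )
        rows.append(
            (fam.family_id, fam.cotwin, fam.father, fam.mother, "0", "1", "cotwin")
        )
    with Path(path).open("w") as fh:
        fh.write("#family_id\tsample\tfather\tmother\tsex\tphenotype\trole\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
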