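"""Synthetic quartet cohorts with a planted-mutation truth table.

The generator emulates the data a discordant monozygotic-twin exome study
produces after variant calling and annotation: one four-sample VCF per
quartet (affected twin, co-twin, father, mother), an ANNOVAR-style
annotation table with five population-frequency columns, per-target read
depth tables for CNV calling, a pedigree file with member roles, gene sets
in GMT format, and a JSON truth table recording every planted post-twinning
SNV/indel and CNV.

The simulation is deliberately simple and fully controlled:

* germline sites are diploid biallelic; each parent is heterozygous with
  probability ``germline_het_rate`` and alleles are transmitted Mendelianly;
  both twins inherit the *same* germline genotype;
* somatic mosaicism is modelled by flipping the genotype of one randomly
  chosen twin at each site with probability ``twin_discordance_rate``;
* planted de novo mutations are heterozygous in the affected twin only and
  absent from the co-twin and both parents — the signature of a
  post-twinning event;
* per-target read depth follows a negative-binomial law with mean
  ``depth_mean`` and dispersion ``depth_dispersion`` (variance
  ``mu + d*mu^2``); dispersion 0 is the noise-free mode with deterministic
  depths and exact 0.5 heterozygous allele fractions.

A record is emitted for *every* simulated site, including sites where the
whole family is homozygous reference, so that twin concordance measured
downstream is an unbiased estimate of ``1 - twin_discordance_rate``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from twinseg.vario import (
    FUNCTIONAL_CLASSES,
    MAF_COLUMNS,
    QuartetFamily,
    write_pedigree,
)

MAF_PROFILES = ("absent", "rare", "common")

_BASES = np.array(list("ACGT"))


class ScenarioError(ValueError):
    """Raised when a cohort scenario violates its invariants."""


@dataclass(frozen=True)
class PlantedDnmSpec:
    """Blueprint for one planted post-twinning de novo mutation per proband.

    ``shared=True`` plants the mutation at the same genomic site with the
    same alleles in every family, creating cross-family recurrence; otherwise
    each family receives a private site.
    """

    gene: str
    functional_class: str = "missense"
    maf_profile: str = "absent"
    shared: bool = False

    def __post_init__(self) -> None:
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ScenarioError(
                f"planted_dnm_spec: functional_class {self.functional_class!r} "
                "not in vocabulary"
            )
        if self.maf_profile not in MAF_PROFILES:
            raise ScenarioError(
                f"planted_dnm_spec: maf_profile {self.maf_profile!r} unknown"
            )


@dataclass(frozen=True)
class PlantedCnv:
    """Truth record for one planted copy-number event (1-based inclusive)."""

    family: str
    carrier: str  # role: proband | cotwin | father | mother
    chrom: str
    start: int
    end: int
    copy_number: int
    overlapping_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ScenarioError(f"cnv_plans: start {self.start} > end {self.end}")
        if self.copy_number == 2:
            raise ScenarioError("cnv_plans: copy_number 2 is the diploid baseline")
        if self.copy_number < 0:
            raise ScenarioError("cnv_plans: copy_number must be >= 0")
        if self.carrier not in ("proband", "cotwin", "father", "mother"):
            raise ScenarioError(f"cnv_plans: unknown carrier role {self.carrier!r}")


def default_dnm_specs() -> list[PlantedDnmSpec]:
    """Default planted-mutation blueprint: three rare protein-altering events.

    One of them is shared across families so that variant- and gene-level
    recurrence have planted positives.
    """
    return [
        PlantedDnmSpec("DNMG001", "missense", "absent", shared=True),
        PlantedDnmSpec("DNMG002", "frameshift", "rare"),
        PlantedDnmSpec("DNMG003", "stopgain", "absent"),
    ]


@dataclass(frozen=True)
class CohortScenario:
    """Study conditions for one synthetic cohort.

    Defaults mirror the six-quartet discordant-twin design: 6 families,
    mean target depth 387.6x, and three planted rare protein-altering
    post-twinning mutations per proband.
    """

    n_families: int = 6
    n_sites: int = 2000
    germline_het_rate: float = 0.25
    twin_discordance_rate: float = 0.0
    n_planted_dnm_per_proband: int = 3
    planted_dnm_spec: tuple[PlantedDnmSpec, ...] = ()
    depth_mean: float = 387.6
    depth_dispersion: float = 0.1
    cnv_plans: tuple[PlantedCnv, ...] = ()
    n_cnv_targets: int = 400
    cnv_target_span: int = 1000
    n_pathways: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("germline_het_rate", "twin_discordance_rate"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ScenarioError(f"{name} must be in [0, 1], got {value}")
        for name in ("n_families", "n_sites", "n_planted_dnm_per_proband",
                     "n_cnv_targets", "n_pathways"):
            if getattr(self, name) < 0:
                raise ScenarioError(f"{name} must be >= 0")
        if self.depth_mean <= 0:
            raise ScenarioError("depth_mean must be positive")
        if self.depth_dispersion < 0:
            raise ScenarioError("depth_dispersion must be >= 0")
        if self.cnv_target_span < 1:
            raise ScenarioError("cnv_target_span must be >= 1")
        specs = self.planted_dnm_spec
        if not specs and self.n_planted_dnm_per_proband > 0:
            specs = tuple(default_dnm_specs())
        if self.n_planted_dnm_per_proband > 0:
            # cycle the blueprint if shorter than the requested count
            specs = tuple(
                specs[i % len(specs)] for i in range(self.n_planted_dnm_per_proband)
            )
        else:
            specs = ()
        object.__setattr__(self, "planted_dnm_spec", specs)
        object.__setattr__(self, "cnv_plans", tuple(self.cnv_plans))

    @property
    def noise_free(self) -> bool:
        return self.depth_dispersion == 0 and self.twin_discordance_rate == 0


@dataclass
class TruthTable:
    """Ground truth of planted events, serializable to JSON."""

    dnms: list[dict] = field(default_factory=list)
    cnvs: list[PlantedCnv] = field(default_factory=list)

    def dnm_keys(self, family_id: str | None = None) -> set[tuple]:
        return {
            (d["family"], d["chrom"], d["pos"], d["ref"], d["alt"])
            for d in self.dnms
            if family_id is None or d["family"] == family_id
        }

    def to_json(self) -> str:
        return json.dumps(
            {
                "dnms": self.dnms,
                "cnvs": [dataclasses.asdict(c) for c in self.cnvs],
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthTable":
        raw = json.loads(text)
        cnvs = [
            PlantedCnv(**{**c, "overlapping_genes": tuple(c["overlapping_genes"])})
            for c in raw["cnvs"]
        ]
        return cls(dnms=raw["dnms"], cnvs=cnvs)


@dataclass
class SyntheticCohort:
    """Paths and truth for one generated cohort directory."""

    root: Path
    scenario: CohortScenario
    families: list[QuartetFamily]
    vcf_paths: dict[str, Path]
    annotation_path: Path
    pedigree_path: Path
    depth_paths: dict[str, Path]
    gene_intervals_path: Path
    gmt_path: Path
    truth: TruthTable
    truth_path: Path

    def family(self, family_id: str) -> QuartetFamily:
        for fam in self.families:
            if fam.family_id == family_id:
                return fam
        raise KeyError(family_id)


def generate_maf_profile(kind: str, rng: np.random.Generator | None = None) -> dict:
    """Five-database MAF vector of a given kind.

    absent: all five frequencies missing; rare: all present and <= 0.10;
    common: at least one database above the 10% exclusion threshold.
    """
    if kind not in MAF_PROFILES:
        raise ScenarioError(f"unknown MAF profile kind {kind!r}")
    if kind == "absent":
        return {name: None for name in MAF_COLUMNS}
    if rng is None:
        values = {"rare": 0.01, "common": 0.25}[kind]
        return {name: values for name in MAF_COLUMNS}
    if kind == "rare":
        return {
            name: round(float(rng.uniform(1e-4, 0.05)), 6) for name in MAF_COLUMNS
        }
    profile = {name: round(float(rng.uniform(0.0, 0.5)), 6) for name in MAF_COLUMNS}
    anchor = MAF_COLUMNS[int(rng.integers(len(MAF_COLUMNS)))]
    profile[anchor] = round(float(rng.uniform(0.15, 0.6)), 6)
    return profile


# ---------------------------------------------------------------------------
# site grid and planted-site placement


def _germline_sites(scenario: CohortScenario, rng: np.random.Generator):
    """Deterministic grid of biallelic SNV sites over autosomes 1-22."""
    n = scenario.n_sites
    chrom_idx = np.arange(n) % 22 + 1
    pos = 100_000 + (np.arange(n) // 22) * 150
    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
    return (
        [str(c) for c in chrom_idx],
        pos.tolist(),
        _BASES[ref_i].tolist(),
        _BASES[alt_i].tolist(),
    )


def _planted_site(spec: PlantedDnmSpec, spec_index: int, family_index: int):
    """Deterministic coordinates/alleles for a planted mutation.

    Shared specs live on chromosome 7 at positions independent of the
    family; private specs live on chromosome 8 at family-specific positions.
    Indels are used for the frameshift / non-frameshift classes.
    """
    if spec.shared:
        chrom, pos = "7", 5_000_000 + spec_index * 100
    else:
        chrom, pos = "8", 5_000_000 + (family_index * 500 + spec_index) * 100
    if spec.functional_class == "frameshift":
        ref, alt = "AT", "A"  # 1-bp coding deletion
    elif spec.functional_class == "nonframeshift_indel":
        ref, alt = "AGTC", "A"
    else:
        ref, alt = "A", "C"
    return chrom, pos, ref, alt


def _cnv_grid(scenario: CohortScenario):
    """Non-overlapping target grid over chromosomes 1-2 plus gene intervals."""
    n = scenario.n_cnv_targets
    span = scenario.cnv_target_span
    half = (n + 1) // 2
    rows = []
    for t in range(n):
        chrom = "1" if t < half else "2"
        within = t if t < half else t - half
        start = 1_000_000 + within * span
        rows.append((chrom, start, start + span - 1))
    genes = []  # gene -> interval covering 10 consecutive targets
    per_gene = 10
    by_chrom: dict[str, list[tuple]] = {}
    for row in rows:
        by_chrom.setdefault(row[0], []).append(row)
    g = 0
    gene_rows = []
    for chrom in sorted(by_chrom):
        targets = by_chrom[chrom]
        for i in range(0, len(targets), per_gene):
            block = targets[i : i + per_gene]
            gene_rows.append((f"CNVG{g:03d}", chrom, block[0][1], block[-1][2]))
            g += 1
    return rows, gene_rows


def _overlapping_genes(gene_rows, chrom: str, start: int, end: int) -> tuple[str, ...]:
    return tuple(
        g for g, c, s, e in gene_rows if c == chrom and s <= end and e >= start
    )


# ---------------------------------------------------------------------------
# per-family genotype simulation


def _simulate_family_genotypes(scenario: CohortScenario, rng: np.random.Generator):
    """Return alt-allele-count vectors (proband, cotwin, father, mother)."""
    n = scenario.n_sites
    r = scenario.germline_het_rate
    father = (rng.random(n) < r).astype(np.int8)
    mother = (rng.random(n) < r).astype(np.int8)
    # Mendelian transmission; both twins inherit the same germline genotype
    from_father = np.where(father == 1, rng.integers(0, 2, size=n), 0).astype(np.int8)
    from_mother = np.where(mother == 1, rng.integers(0, 2, size=n), 0).astype(np.int8)
    germline = from_father + from_mother
    proband = germline.copy()
    cotwin = germline.copy()
    if scenario.twin_discordance_rate > 0:
        flip = rng.random(n) < scenario.twin_discordance_rate
        which = rng.random(n) < 0.5  # True -> proband carries the somatic change
        shift = rng.integers(1, 3, size=n).astype(np.int8)  # to a different genotype
        flipped = (germline + shift) % 3
        proband = np.where(flip & which, flipped, proband)
        cotwin = np.where(flip & ~which, flipped, cotwin)
    return proband, cotwin, father, mother


def _depths(scenario: CohortScenario, rng: np.random.Generator, size: int) -> np.ndarray:
    mu, d = scenario.depth_mean, scenario.depth_dispersion
    if d == 0:
        return np.full(size, int(round(mu)), dtype=np.int64)
    # NB with variance mu + d*mu^2: shape n = 1/d, p = n/(n+mu)
    n_param = 1.0 / d
    p = n_param / (n_param + mu)
    return rng.negative_binomial(n_param, p, size=size).astype(np.int64)


def _alt_depths(
    genotypes: np.ndarray, depths: np.ndarray, scenario: CohortScenario,
    rng: np.random.Generator,
) -> np.ndarray:
    out = np.zeros_like(depths)
    het = genotypes == 1
    hom = genotypes == 2
    if scenario.depth_dispersion == 0:
        out[het] = depths[het] // 2
    else:
        out[het] = rng.binomial(depths[het], 0.5)
    out[hom] = depths[hom]
    return out


_GT_FIELD = {0: "0/0", 1: "0/1", 2: "1/1"}


def _write_family_vcf(
    path: Path,
    family: QuartetFamily,
    chroms: Sequence[str],
    positions: Sequence[int],
    refs: Sequence[str],
    alts: Sequence[str],
    genotype_matrix: np.ndarray,  # (4, n_sites) alt-allele counts
    depth_matrix: np.ndarray,
    alt_depth_matrix: np.ndarray,
) -> None:
    order = sorted(
        range(len(chroms)), key=lambda i: (int(chroms[i]), positions[i], refs[i], alts[i])
    )
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(set(chroms), key=int):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(family.members)
            + "\n"
        )
        for i in order:
            cells = []
            for s in range(4):
                dp = depth_matrix[s, i]
                ad = alt_depth_matrix[s, i]
                cells.append(f"{_GT_FIELD[int(genotype_matrix[s, i])]}:{dp}:{dp - ad},{ad}:99")
            fh.write(
                f"{chroms[i]}\t{positions[i]}\t.\t{refs[i]}\t{alts[i]}\t.\tPASS\t.\t"
                "GT:DP:AD:GQ\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(scenario: CohortScenario, out_dir: str | Path) -> SyntheticCohort:
    """Generate a full synthetic cohort directory.

    Writes one four-sample VCF per family, a shared annotation table
    covering every emitted ALT allele, per-subject depth tables, a
    PED-with-role pedigree, gene intervals and gene sets for the CNV and
    enrichment stages, and the JSON truth table. Identical scenarios
    (including the seed) produce byte-identical outputs.
    """
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    seed_seq = np.random.SeedSequence(scenario.seed)
    site_rng = np.random.default_rng(seed_seq.spawn(1)[0])
    family_seeds = seed_seq.spawn(scenario.n_families + 1)

    chroms, positions, refs, alts = _germline_sites(scenario, site_rng)
    n_germline = scenario.n_sites

    # cohort-wide annotation for germline sites
    class_pool = np.array(
        ["synonymous", "intronic", "missense", "splice_boundary", "stopgain",
         "frameshift", "nonframeshift_indel"]
    )
    class_p = np.array([0.25, 0.30, 0.30, 0.05, 0.03, 0.04, 0.03])
    germline_classes = site_rng.choice(class_pool, size=n_germline, p=class_p)
    germline_common = site_rng.random(n_germline) < 0.7

    families = [
        QuartetFamily(
            family_id=f"FAM{f + 1:02d}",
            proband=f"FAM{f + 1:02d}_proband",
            cotwin=f"FAM{f + 1:02d}_cotwin",
            father=f"FAM{f + 1:02d}_father",
            mother=f"FAM{f + 1:02d}_mother",
        )
        for f in range(scenario.n_families)
    ]

    truth = TruthTable()
    annotation_rows: dict[tuple, dict] = {}
    maf_rng = np.random.default_rng(family_seeds[-1])
    for i in range(n_germline):
        kind = "common" if germline_common[i] else "rare"
        key = (chroms[i], positions[i], refs[i], alts[i])
        annotation_rows[key] = {
            "gene": f"GENE{i // 5:04d}",
            "functional_class": str(germline_classes[i]),
            "hgvs_c": f"c.{i + 1}{refs[i]}>{alts[i]}",
            "hgvs_p": "",
            "maf": generate_maf_profile(kind, maf_rng),
        }

    vcf_paths: dict[str, Path] = {}
    for f, family in enumerate(families):
        rng = np.random.default_rng(family_seeds[f])
        proband, cotwin, father, mother = _simulate_family_genotypes(scenario, rng)

        fam_chroms = list(chroms)
        fam_pos = list(positions)
        fam_refs = list(refs)
        fam_alts = list(alts)
        genos = [proband, cotwin, father, mother]
        extra = []
        for j, spec in enumerate(scenario.planted_dnm_spec):
            chrom, pos, ref, alt = _planted_site(spec, j, f)
            fam_chroms.append(chrom)
            fam_pos.append(pos)
            fam_refs.append(ref)
            fam_alts.append(alt)
            extra.append((1, 0, 0, 0))  # het in proband only
            key = (chrom, pos, ref, alt)
            if key not in annotation_rows:
                annotation_rows[key] = {
                    "gene": spec.gene,
                    "functional_class": spec.functional_class,
                    "hgvs_c": f"c.{pos % 10000}{ref}>{alt}",
                    "hgvs_p": "",
                    "maf": generate_maf_profile(spec.maf_profile, maf_rng),
                }
            truth.dnms.append(
                {
                    "family": family.family_id,
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "gene": spec.gene,
                    "functional_class": spec.functional_class,
                    "maf_profile": spec.maf_profile,
                }
            )
        if extra:
            extra_arr = np.array(extra, dtype=np.int8).T  # (4, n_extra)
            genos = [np.concatenate([g, extra_arr[s]]) for s, g in enumerate(genos)]
        geno_matrix = np.vstack(genos)
        n_total = geno_matrix.shape[1]
        depth_matrix = _depths(scenario, rng, 4 * n_total).reshape(4, n_total)
        alt_depth_matrix = np.vstack(
            [
                _alt_depths(geno_matrix[s], depth_matrix[s], scenario, rng)
                for s in range(4)
            ]
        )
        vcf_path = root / f"{family.family_id}.vcf"
        _write_family_vcf(
            vcf_path, family, fam_chroms, fam_pos, fam_refs, fam_alts,
            geno_matrix, depth_matrix, alt_depth_matrix,
        )
        vcf_paths[family.family_id] = vcf_path

    # annotation table (sorted for determinism)
    annotation_path = root / "annotation.tsv"
    with annotation_path.open("w") as fh:
        fh.write(
            "chrom\tpos\tref\talt\tgene\tfunctional_class\thgvs_c\thgvs_p\t"
            + "\t".join(MAF_COLUMNS)
            + "\n"
        )
        for key in sorted(annotation_rows, key=lambda k: (int(k[0]), k[1], k[2], k[3])):
            row = annotation_rows[key]
            maf_cells = [
                "" if row["maf"][name] is None else f"{row['maf'][name]:.6g}"
                for name in MAF_COLUMNS
            ]
            fh.write(
                "\t".join(
                    [key[0], str(key[1]), key[2], key[3], row["gene"],
                     row["functional_class"], row["hgvs_c"], row["hgvs_p"], *maf_cells]
                )
                + "\n"
            )

    pedigree_path = root / "cohort.ped"
    write_pedigree(families, pedigree_path)

    # depth tables and CNV truth
    target_rows, gene_rows = _cnv_grid(scenario)
    gene_intervals_path = root / "cnv_genes.tsv"
    with gene_intervals_path.open("w") as fh:
        fh.write("gene\tchrom\tstart\tend\n")
        for g, c, s, e in gene_rows:
            fh.write(f"{g}\t{c}\t{s}\t{e}\n")

    plans = []
    for plan in scenario.cnv_plans:
        if not plan.overlapping_genes:
            plan = dataclasses.replace(
                plan,
                overlapping_genes=_overlapping_genes(
                    gene_rows, plan.chrom, plan.start, plan.end
                ),
            )
        plans.append(plan)
    truth.cnvs = plans

    depth_dir = root / "depths"
    depth_dir.mkdir(exist_ok=True)
    depth_paths: dict[str, Path] = {}
    depth_rng = np.random.default_rng(seed_seq.spawn(2)[1])
    for family in families:
        for role, sample in family.roles.items():
            base = _depths(scenario, depth_rng, len(target_rows)).astype(float)
            for plan in plans:
                if plan.family != family.family_id or plan.carrier != role:
                    continue
                for t, (chrom, start, end) in enumerate(target_rows):
                    if chrom == plan.chrom and start <= plan.end and end >= plan.start:
                        base[t] = round(base[t] * plan.copy_number / 2.0)
            p = depth_dir / f"{sample}.tsv"
            with p.open("w") as fh:
                fh.write("chrom\tstart\tend\tdepth\n")
                for (chrom, start, end), depth in zip(target_rows, base):
                    fh.write(f"{chrom}\t{start}\t{end}\t{int(depth)}\n")
            depth_paths[sample] = p

    # gene sets over the germline gene universe plus planted genes
    gmt_path = root / "pathways.gmt"
    genes = sorted({row["gene"] for row in annotation_rows.values()})
    germline_genes = [g for g in genes if g.startswith("GENE")]
    planted_genes = sorted({d["gene"] for d in truth.dnms})
    n_pathways = max(scenario.n_pathways, 1)
    block = max(len(germline_genes) // n_pathways, 1)
    with gmt_path.open("w") as fh:
        for p in range(n_pathways):
            members = germline_genes[p * block : (p + 1) * block]
            members += [g for i, g in enumerate(planted_genes) if i % n_pathways == p]
            if not members:
                continue
            fh.write(f"PWY{p:03d}\tsynthetic pathway\t" + "\t".join(members) + "\n")

    truth_path = root / "truth.json"
    truth_path.write_text(truth.to_json())

    return SyntheticCohort(
        root=root,
        scenario=scenario,
        families=families,
        vcf_paths=vcf_paths,
        annotation_path=annotation_path,
        pedigree_path=pedigree_path,
        depth_paths=depth_paths,
        gene_intervals_path=gene_intervals_path,
        gmt_path=gmt_path,
        truth=truth,
        truth_path=truth_path,
    )
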