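"""Cohort orchestration: QC -> segregation -> recurrence -> CNV -> enrichment.

Runs the full quartet analysis over a cohort directory, writes
tab-separated result tables plus a JSON manifest (config hash, package
version, per-stage record bookkeeping), and is deterministic: the same
config over the same inputs reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from twinseg import __version__
from twinseg.cnvcall import call_family_cnvs, read_depth_table, segments_table
from twinseg.enrich import enrich_families, enrichment_table
from twinseg.recurrence import (
    cnv_gene_report,
    recurrent_cnv_genes,
    recurrent_genes,
    recurrent_variants,
    variant_report,
)
from twinseg.segfilter import (
    FilterConfig,
    apply_annotation_filters,
    events_table,
    segregate_family,
)
from twinseg.twinqc import concordance_table, twin_concordance
from twinseg.vario import read_annotation_table, read_family_vcf, read_gmt, read_pedigree

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage and family context."""


@dataclass
class RunConfig:
    """All inputs and thresholds for one cohort run.

    File paths may be absolute or relative to the config file's directory.
    Paper-stated thresholds are the defaults where the study states them
    (MAF 10%, recurrence in >= 2 families, P < 0.05, q < 0.2); the
    remaining thresholds are documented artifact defaults.
    """

    pedigree: Path
    annotation: Path
    vcfs: dict[str, Path]  # family_id -> VCF
    depths: dict[str, Path] = field(default_factory=dict)  # sample -> depth table
    gene_intervals: Path | None = None
    gmt: Path | None = None
    out_dir: Path = Path("twinseg_run")
    filter: FilterConfig = field(default_factory=FilterConfig)
    min_families: int = 2
    min_recurrent_families: int = 2
    qc_min_gq: int = 20
    qc_min_depth: int = 8
    cnv_min_targets: int = 3
    cnv_gain_threshold: float = 0.3
    cnv_loss_threshold: float = -0.3
    cnv_pseudocount: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        paths = [self.pedigree, self.annotation, *self.vcfs.values(),
                 *self.depths.values()]
        if self.gene_intervals is not None:
            paths.append(self.gene_intervals)
        if self.gmt is not None:
            paths.append(self.gmt)
        for p in paths:
            if not Path(p).exists():
                raise PipelineError(f"configured input does not exist: {p}")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "pedigree": str(self.pedigree),
            "annotation": str(self.annotation),
            "vcfs": {k: str(v) for k, v in sorted(self.vcfs.items())},
            "depths": {k: str(v) for k, v in sorted(self.depths.items())},
            "gene_intervals": None if self.gene_intervals is None else str(self.gene_intervals),
            "gmt": None if self.gmt is None else str(self.gmt),
            "out_dir": str(self.out_dir),
            "filter": {
                **dataclasses.asdict(self.filter),
                "protein_altering_classes": sorted(self.filter.protein_altering_classes),
                "excluded_classes": sorted(self.filter.excluded_classes),
            },
            "min_families": self.min_families,
            "min_recurrent_families": self.min_recurrent_families,
            "qc_min_gq": self.qc_min_gq,
            "qc_min_depth": self.qc_min_depth,
            "cnv_min_targets": self.cnv_min_targets,
            "cnv_gain_threshold": self.cnv_gain_threshold,
            "cnv_loss_threshold": self.cnv_loss_threshold,
            "cnv_pseudocount": self.cnv_pseudocount,
            "seed": self.seed,
        }
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict, base: Path | None = None) -> "RunConfig":
        base = base or Path(".")

        def resolve(p):
            if p is None:
                return None
            p = Path(p)
            return p if p.is_absolute() else base / p

        filt = d.get("filter", {})
        filter_config = FilterConfig(
            maf_threshold=filt.get("maf_threshold", 0.10),
            protein_altering_classes=frozenset(
                filt.get(
                    "protein_altering_classes",
                    FilterConfig().protein_altering_classes,
                )
            ),
            excluded_classes=frozenset(
                filt.get("excluded_classes", FilterConfig().excluded_classes)
            ),
            min_proband_alt_depth=filt.get("min_proband_alt_depth", 4),
            min_proband_depth=filt.get("min_proband_depth", 10),
            max_carrier_alt_fraction=filt.get("max_carrier_alt_fraction", 0.05),
        )
        return cls(
            pedigree=resolve(d["pedigree"]),
            annotation=resolve(d["annotation"]),
            vcfs={k: resolve(v) for k, v in d.get("vcfs", {}).items()},
            depths={k: resolve(v) for k, v in d.get("depths", {}).items()},
            gene_intervals=resolve(d.get("gene_intervals")),
            gmt=resolve(d.get("gmt")),
            out_dir=Path(d.get("out_dir", "twinseg_run")),
            filter=filter_config,
            min_families=d.get("min_families", 2),
            min_recurrent_families=d.get("min_recurrent_families", 2),
            qc_min_gq=d.get("qc_min_gq", 20),
            qc_min_depth=d.get("qc_min_depth", 8),
            cnv_min_targets=d.get("cnv_min_targets", 3),
            cnv_gain_threshold=d.get("cnv_gain_threshold", 0.3),
            cnv_loss_threshold=d.get("cnv_loss_threshold", -0.3),
            cnv_pseudocount=d.get("cnv_pseudocount", 1.0),
            seed=d.get("seed", 0),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        return cls.from_dict(yaml.safe_load(path.read_text()), base=path.parent)

    @classmethod
    def for_cohort(cls, cohort, out_dir: str | Path, **overrides) -> "RunConfig":
        """Build a config straight from a :class:`synthdata.SyntheticCohort`."""
        return cls(
            pedigree=cohort.pedigree_path,
            annotation=cohort.annotation_path,
            vcfs=dict(cohort.vcf_paths),
            depths=dict(cohort.depth_paths),
            gene_intervals=cohort.gene_intervals_path,
            gmt=cohort.gmt_path,
            out_dir=Path(out_dir),
            **overrides,
        )

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_cohort(config: RunConfig) -> Path:
    """Execute every stage over the cohort; returns the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, dict] = {}

    def stage(name: str, family: str | None = None):
        class _Ctx:
            def __enter__(self_inner):
                return None

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineError):
                    where = f"stage {name!r}" + (f", family {family}" if family else "")
                    raise PipelineError(f"{where}: {exc}") from exc
                return False

        return _Ctx()

    families, sample_family = read_pedigree(config.pedigree)
    missing_vcfs = [f.family_id for f in families if f.family_id not in config.vcfs]
    if missing_vcfs:
        raise PipelineError(f"no VCF configured for families {missing_vcfs}")

    with stage("annotation"):
        annotations = read_annotation_table(config.annotation)

    qc_reports = []
    all_events = []
    per_family_counts = {}
    for family in families:
        with stage("read_vcf", family.family_id):
            calls = read_family_vcf(config.vcfs[family.family_id], family)
        with stage("qc", family.family_id):
            qc_reports.append(
                twin_concordance(
                    calls, family, min_gq=config.qc_min_gq, min_depth=config.qc_min_depth
                )
            )
        with stage("segregate", family.family_id):
            seg = segregate_family(calls, family, config.filter)
            events, rejected = apply_annotation_filters(
                seg.post_twinning,
                annotations,
                config.filter,
                family_id=family.family_id,
                evidence=seg.evidence,
                with_rejected=True,
            )
        n_unannotated = len(seg.post_twinning) - len(events) - len(rejected)
        per_family_counts[family.family_id] = {
            "post_twinning_keys": len(seg.post_twinning),
            "pre_twinning_keys": len(seg.pre_twinning),
            "candidates": len(events),
            "rejected_by_annotation": len(rejected),
            "unannotated_dropped": n_unannotated,
        }
        all_events.extend(events)
    counts["segregation"] = per_family_counts

    _write(concordance_table(qc_reports), out / "qc_report.tsv")
    cand_df = events_table(all_events)
    if cand_df.empty:
        cand_df = pd.DataFrame(
            columns=["family_id", "chrom", "pos", "ref", "alt", "gene",
                     "functional_class", "hgvs_c", "hgvs_p"]
        )
    _write(cand_df, out / "candidates.tsv")

    with stage("recurrence"):
        rec_vars = recurrent_variants(all_events, min_families=config.min_families)
        rec_genes = recurrent_genes(all_events, min_families=config.min_families)
    _write(variant_report(rec_vars), out / "recurrent_variants.tsv")
    gene_df = pd.DataFrame(
        {
            "gene": [r.gene for r in rec_genes],
            "n_families": [r.n_families for r in rec_genes],
            "families": ["|".join(sorted(r.families)) for r in rec_genes],
            "n_variants": [r.n_variants for r in rec_genes],
        }
    )
    _write(gene_df, out / "recurrent_genes.tsv")
    counts["recurrence"] = {
        "candidate_events": len(all_events),
        "recurrent_variants": len(rec_vars),
        "recurrent_genes": len(rec_genes),
    }

    # CNV stage: proband against the three healthy members of its family
    all_segments = []
    if config.depths:
        for family in families:
            have = [s for s in family.members if s in config.depths]
            if family.proband not in have or len(have) < 2:
                continue
            with stage("cnv", family.family_id):
                proband_profile = read_depth_table(config.depths[family.proband])
                healthy = [
                    read_depth_table(config.depths[s])
                    for s in (family.cotwin, family.father, family.mother)
                    if s in config.depths
                ]
                all_segments.extend(
                    call_family_cnvs(
                        proband_profile,
                        healthy,
                        subject=family.proband,
                        min_targets=config.cnv_min_targets,
                        gain_threshold=config.cnv_gain_threshold,
                        loss_threshold=config.cnv_loss_threshold,
                        pseudocount=config.cnv_pseudocount,
                    )
                )
        seg_df = segments_table([s for s in all_segments if s.call != "neutral"])
        _write(seg_df, out / "cnv_segments.tsv")
        counts["cnv"] = {
            "segments_total": len(all_segments),
            "segments_called": int((seg_df["call"] != "neutral").sum())
            if not seg_df.empty
            else 0,
        }
        if config.gene_intervals is not None:
            with stage("cnv_recurrence"):
                intervals = pd.read_csv(config.gene_intervals, sep="\t", dtype={"chrom": str})
                rec_cnv = recurrent_cnv_genes(
                    all_segments,
                    intervals,
                    sample_family,
                    min_families=config.min_families,
                )
            _write(cnv_gene_report(rec_cnv), out / "recurrent_cnv_genes.tsv")
            counts["cnv"]["recurrent_cnv_genes"] = len(rec_cnv)

    if config.gmt is not None:
        with stage("enrichment"):
            pathways = read_gmt(config.gmt)
            family_sets = {
                fam.family_id: {
                    e.gene for e in all_events if e.family_id == fam.family_id
                }
                for fam in families
            }
            results = enrich_families(
                family_sets,
                pathways,
                min_recurrent_families=config.min_recurrent_families,
            )
        _write(enrichment_table(results), out / "enrichment.tsv")
        counts["enrichment"] = {
            "pathways": len(pathways),
            "pathways_tested": len(results),
            "significant": sum(r.significant for r in results),
        }

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "version": __version__,
        "counts": counts,
        "outputs": sorted(p.name for p in out.iterdir() if p.suffix == ".tsv"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("run complete: %s", out)
    return out
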