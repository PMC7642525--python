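import pandas as pd
import pytest

from twinseg.synthdata import (
    CohortScenario,
    PlantedCnv,
    PlantedDnmSpec,
    generate_cohort,
)
from twinseg.vario import QuartetFamily


@pytest.fixture
def quartet():
    return QuartetFamily(
        family_id="FAM01",
        proband="FAM01_proband",
        cotwin="FAM01_cotwin",
        father="FAM01_father",
        mother="FAM01_mother",
    )


def make_calls(rows):
    """Genotype-call table from (sample, chrom, pos, ref, alt, gt, depth, alt_depth, gq)."""
    return pd.DataFrame(
        rows,
        columns=["sample", "chrom", "pos", "ref", "alt", "gt", "depth", "alt_depth", "gq"],
    )


def quartet_site(family, pos, gts, depth=30, alt_depths=None, chrom="1", ref="A", alt="C"):
    """One site across the four members; gts/alt_depths ordered as family.members."""
    if alt_depths is None:
        alt_depths = [
            depth // 2 if g == "het" else (depth if g == "hom_alt" else 0) for g in gts
        ]
    return [
        (s, chrom, pos, ref, alt, g, depth, ad, 99)
        for s, g, ad in zip(family.members, gts, alt_depths)
    ]


#: Planted-mutation blueprint exercising every filter outcome: three rare
#: protein-altering events (one shared across families), one common
#: missense (MAF filter) and one synonymous event (class filter).
FIXTURE_DNM_SPECS = (
    PlantedDnmSpec("DNMG001", "missense", "absent", shared=True),
    PlantedDnmSpec("DNMG002", "frameshift", "rare"),
    PlantedDnmSpec("DNMG003", "stopgain", "absent"),
    PlantedDnmSpec("DNMG004", "missense", "common"),
    PlantedDnmSpec("DNMG005", "synonymous", "absent"),
)

#: Two planted losses over the same gene block (CNVG005, chr1 targets 50-59)
#: in different families, one gain elsewhere, and one two-target loss that
#: is below the min_targets=3 floor and must stay uncalled.
FIXTURE_CNV_PLANS = (
    PlantedCnv("FAM01", "proband", "1", 1_050_000, 1_059_999, 1),
    PlantedCnv("FAM03", "proband", "1", 1_050_000, 1_059_999, 0),
    PlantedCnv("FAM02", "proband", "2", 1_020_000, 1_029_999, 3),
    PlantedCnv("FAM04", "proband", "2", 1_050_000, 1_051_999, 1),
)


@pytest.fixture(scope="session")
def noise_free_cohort(tmp_path_factory):
    """Six noise-free quartets with planted DNMs and CNVs."""
    scenario = CohortScenario(
        n_families=6,
        n_sites=400,
        germline_het_rate=0.25,
        twin_discordance_rate=0.0,
        n_planted_dnm_per_proband=5,
        planted_dnm_spec=FIXTURE_DNM_SPECS,
        depth_mean=387.6,
        depth_dispersion=0.0,
        cnv_plans=FIXTURE_CNV_PLANS,
        seed=13,
    )
    return generate_cohort(scenario, tmp_path_factory.mktemp("cohort"))
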