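"""Segregation logic and the three annotation filter criteria."""

import pytest

from twinseg.segfilter import (
    CandidateEvent,
    FilterConfig,
    FilterStep,
    apply_annotation_filters,
    run_family,
    segregate_de_novo,
    segregate_family,
)
from twinseg.vario import (
    AnnotatedVariant,
    read_annotation_table,
    read_family_vcf,
    write_genotype_calls_vcf,
)

from conftest import make_calls, quartet_site


def _ann(functional_class="missense", maf=None, key=("1", 100, "A", "C"), gene="G1"):
    return AnnotatedVariant(
        chrom=key[0], pos=key[1], ref=key[2], alt=key[3], gene=gene,
        functional_class=functional_class, maf=maf or {},
    )


class TestSegregation:
    def test_proband_only_variant_retained(self, quartet):
        calls = make_calls(
            quartet_site(quartet, 100, ["het", "hom_ref", "hom_ref", "hom_ref"],
                         depth=30, alt_depths=[15, 0, 0, 0])
        )
        assert segregate_de_novo(calls, quartet) == {("1", 100, "A", "C")}

    def test_inherited_variant_excluded(self, quartet):
        calls = make_calls(
            quartet_site(quartet, 100, ["het", "hom_ref", "het", "hom_ref"])
        )
        assert segregate_de_novo(calls, quartet) == frozenset()

    def test_shared_by_both_twins_is_pre_twinning(self, quartet):
        calls = make_calls(
            quartet_site(quartet, 100, ["het", "het", "hom_ref", "hom_ref"])
        )
        result = segregate_family(calls, quartet)
        assert result.post_twinning == frozenset()
        assert result.pre_twinning == {("1", 100, "A", "C")}

    def test_missing_carrier_genotype_is_conservatively_excluded(self, quartet):
        calls = make_calls(
            quartet_site(quartet, 100, ["het", "missing", "hom_ref", "hom_ref"])
        )
        assert segregate_de_novo(calls, quartet) == frozenset()

    def test_carrier_alt_reads_above_fraction_disqualify(self, quartet):
        calls = make_calls(
            quartet_site(quartet, 100, ["het", "hom_ref", "hom_ref", "hom_ref"],
                         depth=30, alt_depths=[15, 3, 0, 0])  # cotwin 10% alt reads
        )
        assert segregate_de_novo(calls, quartet) == frozenset()
        loose = FilterConfig(max_carrier_alt_fraction=0.15)
        assert segregate_de_novo(calls, quartet, loose) == {("1", 100, "A", "C")}

    def test_weak_proband_evidence_excluded(self, quartet):
        calls = make_calls(
            quartet_site(quartet, 100, ["het", "hom_ref", "hom_ref", "hom_ref"],
                         depth=6, alt_depths=[3, 0, 0, 0])
        )
        config = FilterConfig(min_proband_depth=10, min_proband_alt_depth=4)
        assert segregate_de_novo(calls, quartet, config) == frozenset()

    def test_absent_member_error_names_role(self, quartet):
        calls = make_calls(
            [r for r in quartet_site(quartet, 100, ["het"] * 4) if r[0] != quartet.mother]
        )
        with pytest.raises(ValueError, match="mother"):
            segregate_de_novo(calls, quartet)


class TestAnnotationFilters:
    def test_common_missense_excluded_by_frequency(self):
        keys = [("1", 100, "A", "C")]
        anns = [_ann("missense", {"maf_exac": 0.15})]
        passed, rejected = apply_annotation_filters(keys, anns, with_rejected=True)
        assert passed == []
        assert rejected[0].failed_filters == ("population_maf",)

    def test_boundary_frequency_not_excluded(self):
        """Exclusion requires strictly more than 10% in some database."""
        keys = [("1", 100, "A", "C")]
        anns = [_ann("missense", {"maf_exac": 0.10, "maf_1000g": 0.10})]
        assert len(apply_annotation_filters(keys, anns)) == 1

    def test_synonymous_excluded_by_class(self):
        keys = [("1", 100, "A", "C")]
        passed, rejected = apply_annotation_filters(
            keys, [_ann("synonymous")], with_rejected=True
        )
        assert passed == []
        assert set(rejected[0].failed_filters) == {
            "protein_altering_class", "excluded_class",
        }

    def test_rare_frameshift_retained_with_full_provenance(self):
        keys = [("1", 100, "AT", "A")]
        anns = [_ann("frameshift", key=("1", 100, "AT", "A"))]
        (event,) = apply_annotation_filters(keys, anns, family_id="FAM01")
        assert event.functional_class == "frameshift"
        assert [s.name for s in event.provenance] == [
            "segregation", "protein_altering_class", "excluded_class", "population_maf",
        ]
        assert all(s.passed for s in event.provenance)

    def test_absent_maf_never_triggers_exclusion(self):
        keys = [("1", 100, "A", "C")]
        anns = [_ann("missense", {name: None for name in
                                  ("maf_1000g", "maf_hapmap_chb", "maf_esp",
                                   "maf_dbsnp", "maf_exac")})]
        assert len(apply_annotation_filters(keys, anns)) == 1

    def test_unannotated_keys_dropped(self):
        passed = apply_annotation_filters([("1", 999, "A", "C")], [])
        assert passed == []

    def test_maf_threshold_monotonicity(self):
        """Loosening the MAF threshold upward never removes events."""
        keys = [("1", p, "A", "C") for p in (1, 2, 3, 4)]
        anns = [
            _ann("missense", {"maf_exac": maf}, key=k)
            for maf, k in zip([0.01, 0.08, 0.2, 0.6], keys)
        ]
        previous: set = set()
        for threshold in (0.05, 0.10, 0.30, 1.0):
            config = FilterConfig(maf_threshold=threshold)
            kept = {e.key for e in apply_annotation_filters(keys, anns, config)}
            assert previous <= kept
            previous = kept


class TestCandidateEventInvariant:
    def test_failed_provenance_rejected(self):
        with pytest.raises(ValueError, match="population_maf"):
            CandidateEvent(
                family_id="F", chrom="1", pos=1, ref="A", alt="C", gene="G",
                functional_class="missense",
                provenance=(FilterStep("population_maf", False, ""),),
            )

    def test_config_class_sets_must_be_disjoint(self):
        with pytest.raises(ValueError, match="overlap"):
            FilterConfig(
                protein_altering_classes=frozenset({"missense"}),
                excluded_classes=frozenset({"missense"}),
            )


class TestRunFamily:
    def test_empty_vcf_yields_empty_list(self, tmp_path, quartet):
        calls = make_calls([])
        vcf = tmp_path / "empty.vcf"
        write_genotype_calls_vcf(calls, vcf, samples=list(quartet.members))
        anno = tmp_path / "anno.tsv"
        anno.write_text(
            "chrom\tpos\tref\talt\tgene\tfunctional_class\thgvs_c\thgvs_p\t"
            "maf_1000g\tmaf_hapmap_chb\tmaf_esp\tmaf_dbsnp\tmaf_exac\n"
        )
        assert run_family(vcf, anno, quartet) == []

    def test_recovers_exactly_planted_protein_altering_rare(self, noise_free_cohort):
        truth = noise_free_cohort.truth
        config = FilterConfig()
        for family in noise_free_cohort.families:
            events = run_family(
                noise_free_cohort.vcf_paths[family.family_id],
                noise_free_cohort.annotation_path,
                family,
                config,
            )
            expected = {
                (d["chrom"], d["pos"], d["ref"], d["alt"])
                for d in truth.dnms
                if d["family"] == family.family_id
                and d["functional_class"] in config.protein_altering_classes
                and d["maf_profile"] != "common"
            }
            assert {e.key for e in events} == expected

    def test_planted_synonymous_dnm_absent_from_output(self, noise_free_cohort):
        family = noise_free_cohort.families[0]
        events = run_family(
            noise_free_cohort.vcf_paths[family.family_id],
            noise_free_cohort.annotation_path,
            family,
        )
        synonymous_truth = {
            (d["chrom"], d["pos"], d["ref"], d["alt"])
            for d in noise_free_cohort.truth.dnms
            if d["family"] == family.family_id and d["functional_class"] == "synonymous"
        }
        assert synonymous_truth
        assert not synonymous_truth & {e.key for e in events}


def brute_force_candidates(calls, family, annotations, config):
    """Independent naive re-check of every criterion, site by site."""
    by_key = {}
    for row in calls.itertuples(index=False):
        by_key.setdefault((row.chrom, row.pos, row.ref, row.alt), {})[row.sample] = row
    ann_by_key = {a.key: a for a in annotations}
    out = set()
    for key, members in by_key.items():
        rows = {role: members.get(sample) for role, sample in family.roles.items()}
        if any(r is None for r in rows.values()):
            continue
        p = rows["proband"]
        if p.gt not in ("het", "hom_alt"):
            continue
        if p.alt_depth < config.min_proband_alt_depth or p.depth < config.min_proband_depth:
            continue
        clean = True
        for role in ("cotwin", "father", "mother"):
            r = rows[role]
            frac = r.alt_depth / r.depth if r.depth > 0 else 0.0
            if r.gt != "hom_ref" or frac > config.max_carrier_alt_fraction:
                clean = False
        if not clean:
            continue
        ann = ann_by_key.get(key)
        if ann is None:
            continue
        if ann.functional_class not in config.protein_altering_classes:
            continue
        if ann.functional_class in config.excluded_classes:
            continue
        present = [v for v in ann.maf.values() if v is not None]
        if any(v > config.maf_threshold for v in present):
            continue
        out.add(key)
    return out


class TestOracleEquivalence:
    def test_matches_naive_reimplementation_on_noisy_cohort(self, tmp_path):
        from twinseg.synthdata import CohortScenario, generate_cohort

        scenario = CohortScenario(
            n_families=2, n_sites=600, twin_discordance_rate=0.02,
            depth_dispersion=0.2, germline_het_rate=0.3, seed=23,
        )
        cohort = generate_cohort(scenario, tmp_path / "c")
        annotations = read_annotation_table(cohort.annotation_path)
        config = FilterConfig()
        for family in cohort.families:
            calls = read_family_vcf(cohort.vcf_paths[family.family_id], family)
            seg = segregate_family(calls, family, config)
            events = apply_annotation_filters(seg.post_twinning, annotations, config,
                                              family_id=family.family_id)
            assert {e.key for e in events} == brute_force_candidates(
                calls, family, annotations, config
            )
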