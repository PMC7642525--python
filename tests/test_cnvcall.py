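"""Family-reference CNV calling: reference build, ratios, segmentation."""

import math

import numpy as np
import pandas as pd
import pytest

from twinseg.cnvcall import (
    NORM_MEAN_DEPTH,
    GridMismatchError,
    build_family_reference,
    call_family_cnvs,
    canonicalize_targets,
    log2_ratios,
    read_depth_table,
    segment_and_call,
)


def profile(depths, chrom="1", span=1000):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": [1_000_000 + i * span for i in range(len(depths))],
            "end": [1_000_000 + (i + 1) * span - 1 for i in range(len(depths))],
            "depth": depths,
        }
    )


class TestFamilyReference:
    def test_identical_members_reference_equals_each(self):
        members = [profile([100] * 20) for _ in range(3)]
        ref = build_family_reference(members)
        assert np.allclose(ref["ref_depth"], NORM_MEAN_DEPTH)
        assert np.allclose(ref["spread"], 0.0)
        assert not ref["masked"].any()

    def test_single_member_reference_is_that_profile(self):
        ref = build_family_reference([profile([50, 100, 150, 100])])
        expected = np.array([50, 100, 150, 100]) * (NORM_MEAN_DEPTH / 100)
        assert np.allclose(ref["ref_depth"], expected)

    def test_median_resists_outlier_member(self):
        # member 3 has a 4x spike at target 5; after per-member normalization
        # the reference at that target must track the two typical members
        flat = [100.0] * 20
        spiked = flat.copy()
        spiked[5] = 400.0
        members = [profile(flat), profile(flat), profile(spiked)]
        ref = build_family_reference(members)
        assert math.isclose(ref["ref_depth"][5], NORM_MEAN_DEPTH, rel_tol=1e-9)

    def test_zero_median_targets_masked(self):
        ref = build_family_reference([profile([0, 100, 100, 100])] * 2)
        assert bool(ref["masked"][0])
        assert not ref["masked"][1:].any()

    def test_grid_mismatch_reported(self):
        a, b = profile([1] * 5), profile([1] * 5, span=2000)
        with pytest.raises(GridMismatchError, match="mismatch"):
            build_family_reference([a, b])


class TestLog2Ratios:
    def test_identical_profiles_give_zero(self):
        ref = build_family_reference([profile([120] * 10)] * 3)
        ratios = log2_ratios(profile([120] * 10), ref)
        assert np.allclose(ratios["log2_ratio"], 0.0)

    def test_half_depth_region_near_minus_one(self):
        depths = [100.0] * 200
        ref = build_family_reference([profile(depths)] * 3)
        lost = depths.copy()
        for i in range(50, 60):
            lost[i] = 50.0
        ratios = log2_ratios(profile(lost), ref)
        region = ratios["log2_ratio"][50:60]
        assert np.all(np.abs(region - (-1.0)) < 0.08)  # pseudocount + renorm slack

    def test_one_and_a_half_fold_region_near_0585(self):
        depths = [100.0] * 200
        ref = build_family_reference([profile(depths)] * 3)
        gained = depths.copy()
        for i in range(50, 60):
            gained[i] = 150.0
        ratios = log2_ratios(profile(gained), ref)
        region = ratios["log2_ratio"][50:60]
        assert np.all(np.abs(region - math.log2(1.5)) < 0.06)

    def test_doubling_all_depths_leaves_ratios_unchanged(self):
        rng = np.random.default_rng(3)
        depths = rng.integers(50, 200, size=50).astype(float)
        members = [profile(rng.integers(50, 200, size=50).astype(float)) for _ in range(3)]
        ref1 = build_family_reference(members)
        ref2 = build_family_reference([m.assign(depth=m["depth"] * 2) for m in members])
        r1 = log2_ratios(profile(depths), ref1)
        r2 = log2_ratios(profile(depths * 2), ref2)
        assert np.array_equal(r1["log2_ratio"], r2["log2_ratio"])

    def test_all_masked_rejected(self):
        ref = build_family_reference([profile([1, 1, 1])])
        ref["masked"] = True
        with pytest.raises(ValueError, match="masked"):
            log2_ratios(profile([10, 10, 10]), ref)


class TestSegmentation:
    @staticmethod
    def _track(values, chrom="1"):
        return profile(values, chrom=chrom).drop(columns="depth").assign(
            log2_ratio=values
        )

    def test_flat_zero_track_has_no_calls(self):
        segments = segment_and_call(self._track([0.0] * 50))
        assert all(s.call == "neutral" for s in segments)

    def test_ten_target_loss_amid_zeros_is_one_segment(self):
        values = [0.0] * 20 + [-1.0] * 10 + [0.0] * 20
        segments = segment_and_call(self._track(values), min_targets=3)
        losses = [s for s in segments if s.call == "loss"]
        assert len(losses) == 1
        assert losses[0].n_targets == 10
        assert losses[0].start == 1_000_000 + 20 * 1000
        assert losses[0].end == 1_000_000 + 30 * 1000 - 1
        assert math.isclose(losses[0].mean_log2_ratio, -1.0)

    def test_runs_shorter_than_min_targets_demoted(self):
        values = [0.0] * 10 + [1.0] * 2 + [0.0] * 10
        segments = segment_and_call(self._track(values), min_targets=3)
        assert all(s.call == "neutral" for s in segments)
        assert len(segments) == 1  # demoted run merges back into one neutral segment

    def test_segments_never_span_chromosomes(self):
        track = pd.concat(
            [self._track([-1.0] * 5, chrom="1"), self._track([-1.0] * 5, chrom="2")],
            ignore_index=True,
        )
        losses = [s for s in segment_and_call(track, min_targets=3) if s.call == "loss"]
        assert {s.chrom for s in losses} == {"1", "2"}

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError, match="thresholds"):
            segment_and_call(self._track([0.0] * 5), gain_threshold=-0.1)

    def test_permuted_target_order_canonicalized(self):
        rng = np.random.default_rng(11)
        depths = [100.0] * 30
        for i in range(10, 15):
            depths[i] = 50.0
        members = [profile([100.0] * 30)] * 3
        ordered = call_family_cnvs(profile(depths), members, subject="s")
        shuffled_profile = profile(depths).sample(frac=1, random_state=1).reset_index(drop=True)
        shuffled = call_family_cnvs(shuffled_profile, members, subject="s")
        assert ordered == shuffled


class TestPlantedRecovery:
    def test_noise_free_planted_cnvs_recovered_exactly(self, noise_free_cohort):
        """Every planted CNV spanning >= 3 targets is called with the right
        direction and nothing is called outside planted intervals."""
        truth = {
            (c.family, c.chrom, c.start, c.end): ("loss" if c.copy_number < 2 else "gain")
            for c in noise_free_cohort.truth.cnvs
        }
        for family in noise_free_cohort.families:
            proband = read_depth_table(noise_free_cohort.depth_paths[family.proband])
            healthy = [
                read_depth_table(noise_free_cohort.depth_paths[s])
                for s in (family.cotwin, family.father, family.mother)
            ]
            called = [
                s
                for s in call_family_cnvs(proband, healthy, subject=family.proband)
                if s.call != "neutral"
            ]
            expected = {
                (chrom, start, end): call
                for (fam, chrom, start, end), call in truth.items()
                if fam == family.family_id
                and (end - start + 1) // 1000 >= 3  # 1 kb targets, min_targets=3
            }
            assert {(s.chrom, s.start, s.end): s.call for s in called} == expected

    def test_sub_minimum_planted_cnv_stays_uncalled(self, noise_free_cohort):
        family = noise_free_cohort.family("FAM04")  # two-target planted loss
        proband = read_depth_table(noise_free_cohort.depth_paths[family.proband])
        healthy = [
            read_depth_table(noise_free_cohort.depth_paths[s])
            for s in (family.cotwin, family.father, family.mother)
        ]
        called = [s for s in call_family_cnvs(proband, healthy) if s.call != "neutral"]
        assert called == []

    def test_depth_table_reader_validates(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("chrom\tstart\tend\n1\t1\t10\n")
        with pytest.raises(ValueError, match="depth"):
            read_depth_table(path)

    def test_overlapping_targets_rejected(self):
        bad = profile([1, 1])
        bad.loc[1, "start"] = bad.loc[0, "end"]
        with pytest.raises(ValueError, match="overlap"):
            canonicalize_targets(bad)
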