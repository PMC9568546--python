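"""Candidate filtering, tissue classification, and cohort summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonoscope import (
    FilterConfig,
    SimConfig,
    classify_profile,
    clone_fraction,
    filter_candidates,
    profiles_from_observations,
    simulate,
    summarize_cohort,
)
from clonoscope.filtering import GERMLINE_VAF, LOW_VAF, READ_SUPPORT, RECURRENCE
from clonoscope.model import Variant, VariantObservation, VariantProfile


def _bm(animal, pos, alt_reads, depth=500, chrom="chr1"):
    return VariantObservation(
        animal_id=animal, tissue="BM", chrom=chrom, pos=pos,
        ref="A", alt="G", alt_reads=alt_reads, depth=depth,
    )


class TestFilterCandidates:
    def test_germline_vaf_rejected_with_precedence(self):
        res = filter_candidates([_bm("m1", 100, 200, 500)])  # VAF 0.40
        assert res.rejections[("m1", "chr1:100:A>G")] == GERMLINE_VAF

    def test_boundary_vafs_survive(self):
        # VAF exactly 0.02 (and >= 6 reads) and exactly 0.35 both survive
        obs = [_bm("m1", 100, 10, 500), _bm("m1", 200, 175, 500)]
        res = filter_candidates(obs, n_animals=18)
        assert {v.pos for v in res.survivors["m1"]} == {100, 200}

    def test_read_support_boundary(self):
        # 6 alt reads survive, 5 do not, at VAF inside the window
        obs = [_bm("m1", 100, 6, 250), _bm("m1", 200, 5, 220)]
        res = filter_candidates(obs, n_animals=18)
        assert [v.pos for v in res.survivors["m1"]] == [100]
        assert res.rejections[("m1", "chr1:200:A>G")] == READ_SUPPORT

    def test_low_vaf_rejected(self):
        res = filter_candidates([_bm("m1", 100, 6, 1000)])  # VAF 0.006
        assert res.rejections[("m1", "chr1:100:A>G")] == LOW_VAF

    def test_recurrent_variant_rejected(self):
        # detected in 17 of 18 animals: fraction 0.94 > 0.5
        obs = [_bm(f"m{i}", 100, 50, 500) for i in range(17)]
        obs.append(_bm("m17", 999, 50, 500))  # 18th animal, other site
        res = filter_candidates(obs)
        assert all(
            res.rejections[(f"m{i}", "chr1:100:A>G")] == RECURRENCE
            for i in range(17)
        )

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError, match="empty cohort"):
            filter_candidates([])

    @given(
        lo=st.floats(0.02, 0.1),
        hi=st.floats(0.2, 0.35),
        shrink=st.floats(0.0, 0.05),
    )
    @settings(max_examples=30, deadline=None)
    def test_shrinking_window_never_adds_survivors(self, lo, hi, shrink):
        rng = np.random.default_rng(1)
        obs = [
            _bm("m1", 100 * (i + 1), int(v * 500), 500)
            for i, v in enumerate(rng.uniform(0, 0.5, size=30))
        ]
        wide = filter_candidates(obs, FilterConfig(vaf_min=lo, vaf_max=hi), n_animals=18)
        narrow = filter_candidates(
            obs, FilterConfig(vaf_min=lo + shrink, vaf_max=hi - shrink), n_animals=18
        )
        assert set(narrow.survivors["m1"]) <= set(wide.survivors["m1"])


def _profile(bm, nh_vafs, animal="m1"):
    tissues = {"BM": (bm, 30000)}
    for t, v in nh_vafs.items():
        tissues[t] = (v, 30000)
    return VariantProfile(
        animal_id=animal, variant=Variant("chr1", 100, "A", "G"),
        vaf_by_tissue=tissues,
    )


class TestClassifyProfile:
    def test_blood_expanded_mosaic(self):
        # detected at low VAF in brain/testis/thyroid, 10x expanded in BM
        p = _profile(0.29, {"brain": 0.029, "testis": 0.025, "thyroid": 0.03})
        assert classify_profile(p) == "CH_MOSAIC"

    def test_hematopoietic_restricted(self):
        p = _profile(0.14, {"brain": 0.0, "testis": 0.0, "tail": 0.0003})
        assert classify_profile(p) == "CH_NONMOSAIC"

    def test_uniform_mosaic_not_ch(self):
        p = _profile(0.10, {"tail": 0.10, "brain": 0.10})
        assert classify_profile(p) == "MOSAIC_NOT_CH"

    def test_ratio_between_folds_stays_unclassified(self):
        p = _profile(0.20, {"brain": 0.05})  # ratio 4, between 3 and 5
        assert classify_profile(p) == "UNCLASSIFIED"
        assert "ratio" in p.class_reason

    def test_no_reference_tissue_unclassified_with_reason(self):
        p = _profile(0.2, {})
        assert classify_profile(p) == "UNCLASSIFIED"
        assert "non-hematopoietic" in p.class_reason

    def test_labels_partition_survivors(self):
        cohort = simulate(SimConfig(seed=5, n_irradiated=4, n_control=2))
        profiles = profiles_from_observations(cohort.observations)
        labels = [classify_profile(p) for p in profiles if p.bm_vaf is not None]
        from clonoscope.model import CLASS_LABELS

        assert all(lab in CLASS_LABELS for lab in labels)
        counts = {lab: labels.count(lab) for lab in CLASS_LABELS}
        assert sum(counts.values()) == len(labels)

    def test_simulator_truth_recovered_noise_free(self):
        """>= 99% of true class labels recovered at default thresholds."""
        total = correct = 0
        seed = 0
        while total < 1000:
            seed += 1
            cohort = simulate(
                SimConfig(seed=seed, noise="none", n_irradiated=6, n_control=2)
            )
            profiles = {
                (p.animal_id, p.variant.key): p
                for p in profiles_from_observations(cohort.observations)
            }
            for aid, muts in cohort.truth.mutations.items():
                for m in muts:
                    lab = classify_profile(profiles[(aid, m.variant.key)])
                    total += 1
                    correct += lab == m.true_class
        assert correct / total >= 0.99


class TestCloneFraction:
    @pytest.mark.parametrize(
        "vaf,expected", [(0.29, 0.58), (0.1, 0.20), (0.0, 0.0), (0.5, 1.0)]
    )
    def test_doubles_vaf(self, vaf, expected):
        assert clone_fraction(vaf) == pytest.approx(expected)

    def test_rejects_vaf_above_half(self):
        with pytest.raises(ValueError, match="heterozygous"):
            clone_fraction(0.51)


class TestSummarizeCohort:
    def test_tabulated_cohort_counts_and_means(self, reference_fixtures):
        fx = reference_fixtures
        res = filter_candidates(fx.table1_observations, n_animals=len(fx.animals))
        surviving = {(a, v.key) for a, vs in res.survivors.items() for v in vs}
        profiles = [
            p
            for p in profiles_from_observations(fx.table1_observations)
            if (p.animal_id, p.variant.key) in surviving
        ]
        for p in profiles:
            classify_profile(p)
        summary = summarize_cohort(profiles, fx.animals)
        assert summary.total("CH_NONMOSAIC") == 65
        assert summary.total("MOSAIC_NOT_CH") == 9
        assert summary.total("CH_MOSAIC") == 5
        irr = summary.group_means.loc["IRRADIATED"]
        assert irr["CH_NONMOSAIC"] == pytest.approx(65 / 12)
        # mean CH-associated per irradiated mouse = (5 + 65) / 12 = 5.8(3)
        assert irr["CH_MOSAIC"] + irr["CH_NONMOSAIC"] == pytest.approx(70 / 12)
        assert summary.n_with_ch == {"IRRADIATED": 11, "CONTROL": 0}
        assert summary.n_with_ch_high_vaf == {"IRRADIATED": 9, "CONTROL": 0}
        # sub-counts never exceed counts
        for lab in ("MOSAIC_NOT_CH", "CH_MOSAIC", "CH_NONMOSAIC"):
            assert (
                summary.per_animal[f"{lab}_gt01"] <= summary.per_animal[lab]
            ).all()

    def test_empty_cohort_all_zero(self, reference_fixtures):
        summary = summarize_cohort([], reference_fixtures.animals)
        assert (summary.per_animal.to_numpy() == 0).all()
        assert (summary.group_means.to_numpy() == 0).all()

    def test_unknown_animal_rejected(self, reference_fixtures):
        p = _profile(0.1, {"tail": 0.1}, animal="nosuch")
        p.class_label = "MOSAIC_NOT_CH"
        with pytest.raises(KeyError, match="nosuch"):
            summarize_cohort([p], reference_fixtures.animals)

    def test_unclassified_profile_rejected(self, reference_fixtures):
        p = _profile(0.1, {"tail": 0.1}, animal="33")
        with pytest.raises(ValueError, match="unclassified"):
            summarize_cohort([p], reference_fixtures.animals)
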