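"""Synthetic cohort generator: demographics, growth laws, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gratio_dev import cohort as cohort_mod
from gratio_dev.cohort import (CohortSpec, GrowthLaw, LogCurve, NoiseSD,
                               SigmoidCurve, SubjectRecord, build_atlas,
                               default_cohort_ages, evaluate_growth,
                               generate_cohort, sample_log_uniform_ages)
from conftest import STUDY_AGES


class TestDefaultCohort:
    def test_eighteen_subjects_with_study_ages(self):
        records = default_cohort_ages()
        assert len(records) == 18
        assert sorted(r.age_days for r in records) == STUDY_AGES
        assert min(r.age_days for r in records) == 102
        assert max(r.age_days for r in records) == 2713

    def test_sex_distribution(self):
        records = default_cohort_ages()
        assert sum(r.sex == "M" for r in records) == 13
        assert sum(r.sex == "F" for r in records) == 5

    def test_subject_ids_unique(self):
        ids = [r.subject_id for r in default_cohort_ages()]
        assert len(set(ids)) == len(ids)


class TestEvaluateGrowth:
    def test_sigmoid_step_limit(self):
        law = GrowthLaw(1, "r", "left",
                        SigmoidCurve(lower=0.0, upper=0.3, midpoint_days=500, rate=50.0),
                        LogCurve(0.0, 0.5))
        vfm, _, _ = evaluate_growth(law, 1000.0)
        assert vfm == pytest.approx(0.3, abs=1e-12)

    def test_sigmoid_midpoint_is_half_range(self):
        law = GrowthLaw(1, "r", "left",
                        SigmoidCurve(lower=0.0, upper=0.3, midpoint_days=500, rate=0.005),
                        LogCurve(0.0, 0.5))
        vfm, _, _ = evaluate_growth(law, 500.0)
        assert vfm == pytest.approx(0.15, abs=1e-12)

    def test_zero_slope_gives_constant_nu_ic(self):
        law = GrowthLaw(1, "r", "left", SigmoidCurve(0, 0.3, 500, 0.005),
                        LogCurve(slope=0.0, intercept=0.42))
        for age in (50.0, 500.0, 5000.0):
            assert evaluate_growth(law, age)[1] == pytest.approx(0.42)

    def test_nonpositive_age_rejected(self):
        law = GrowthLaw(1, "r", "left", SigmoidCurve(0, 0.3, 500, 0.005),
                        LogCurve(0.05, 0.3))
        with pytest.raises(ValueError):
            evaluate_growth(law, 0.0)
        with pytest.raises(ValueError):
            evaluate_growth(law, -10.0)

    @settings(derandomize=True, max_examples=100)
    @given(lower=st.floats(0, 0.3), upper=st.floats(0, 0.6),
           midpoint=st.floats(50, 2000), rate=st.floats(1e-4, 0.1),
           slope=st.floats(-0.1, 0.2), intercept=st.floats(-0.5, 1.2),
           nuiso=st.floats(0, 1), age=st.floats(1, 10000))
    def test_outputs_always_fractions(self, lower, upper, midpoint, rate,
                                      slope, intercept, nuiso, age):
        law = GrowthLaw(1, "r", "left", SigmoidCurve(lower, upper, midpoint, rate),
                        LogCurve(slope, intercept), nuiso_level=nuiso)
        for v in evaluate_growth(law, age):
            assert 0.0 <= v <= 1.0


def test_default_laws_nondecreasing_in_age(default_laws):
    ages = np.geomspace(80, 9000, 60)
    for law in default_laws:
        vfm, nu_ic, _ = evaluate_growth(law, ages)
        assert np.all(np.diff(vfm) >= -1e-12), law.region
        assert np.all(np.diff(nu_ic) >= -1e-12), law.region


def test_default_laws_cover_every_atlas_label(default_laws):
    labels, regions = build_atlas()
    present = set(np.unique(labels)) - {0}
    assert present == {l.region_id for l in default_laws}
    assert len(regions) == 23  # 10 bilateral pairs + 3 midline


def _tiny_spec(laws, noise=None, seed=0):
    if noise is not None:
        laws = [GrowthLaw(l.region_id, l.region, l.hemisphere, l.vfm_curve,
                          l.nuic_curve, l.nuiso_level, noise) for l in laws]
    subjects = [SubjectRecord("a", "M", 120.0), SubjectRecord("b", "F", 900.0)]
    return CohortSpec(subjects=subjects, growth_laws=laws,
                      grid_shape=(16, 16, 16), rng_seed=seed)


class TestGenerateCohort:
    def test_zero_noise_voxels_equal_expectation(self, default_laws):
        spec = _tiny_spec(default_laws, noise=NoiseSD(0.0, 0.0, 0.0))
        cohort = generate_cohort(spec)
        law = default_laws[0]
        sel = cohort.labels == law.region_id
        for subj in spec.subjects:
            mu = evaluate_growth(law, subj.age_days)
            pm = cohort.maps[subj.subject_id]
            for vol, expected in zip((pm.vfm, pm.nu_ic, pm.nu_iso), mu):
                assert np.all(vol[sel] == np.clip(expected, 0, 1))
        assert cohort.clamp_fraction == 0.0

    def test_bit_identical_under_same_seed(self, default_laws):
        c1 = generate_cohort(_tiny_spec(default_laws, seed=9))
        c2 = generate_cohort(_tiny_spec(default_laws, seed=9))
        for sid in c1.maps:
            assert np.array_equal(c1.maps[sid].vfm, c2.maps[sid].vfm)
            assert np.array_equal(c1.maps[sid].nu_ic, c2.maps[sid].nu_ic)
            assert np.array_equal(c1.maps[sid].nu_iso, c2.maps[sid].nu_iso)
        assert np.array_equal(c1.labels, c2.labels)

    def test_different_seeds_differ(self, default_laws):
        c1 = generate_cohort(_tiny_spec(default_laws, seed=1))
        c2 = generate_cohort(_tiny_spec(default_laws, seed=2))
        assert not np.array_equal(c1.maps["a"].vfm, c2.maps["a"].vfm)

    def test_all_masked_values_are_fractions(self, small_cohort):
        for pm in small_cohort.maps.values():
            for vol in (pm.vfm, pm.nu_ic, pm.nu_iso):
                vals = vol[pm.mask]
                assert np.isfinite(vals).all()
                assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_clamp_rate_below_one_percent_at_default_noise(self, small_cohort):
        assert small_cohort.clamp_fraction < 0.01

    def test_atlas_shared_across_subjects(self, small_cohort):
        masks = [pm.mask for pm in small_cohort.maps.values()]
        for m in masks[1:]:
            assert np.array_equal(m, masks[0])

    def test_region_without_law_is_configuration_error(self, default_laws):
        spec = _tiny_spec(default_laws)
        spec.regions = cohort_mod.default_region_definitions()
        spec.growth_laws = spec.growth_laws[:-1]  # atlas keeps the region
        with pytest.raises(ValueError, match="without a GrowthLaw"):
            generate_cohort(spec)

    def test_duplicate_subject_ids_rejected(self, default_laws):
        with pytest.raises(ValueError, match="unique"):
            CohortSpec(subjects=[SubjectRecord("a", "M", 120.0)] * 2,
                       growth_laws=default_laws, grid_shape=(16, 16, 16))


def test_log_uniform_sampler_bounds_and_determinism():
    rng = np.random.default_rng(3)
    recs = sample_log_uniform_ages(50, rng)
    ages = np.array([r.age_days for r in recs])
    assert np.all((ages >= 100) & (ages <= 2700))
    recs2 = sample_log_uniform_ages(50, np.random.default_rng(3))
    assert [r.age_days for r in recs2] == [r.age_days for r in recs]


def test_cohort_roundtrip_through_disk(tmp_path, small_cohort):
    cohort_mod.write_cohort(small_cohort, tmp_path)
    pm = cohort_mod.load_subject_maps(tmp_path, small_cohort.subjects[0].subject_id)
    orig = small_cohort.maps[small_cohort.subjects[0].subject_id]
    np.testing.assert_allclose(pm.vfm, orig.vfm, atol=1e-7)  # float32 on disk
    assert np.array_equal(pm.mask, orig.mask)
    assert (tmp_path / "subjects.csv").exists()
    assert (tmp_path / "growth_truth.yaml").exists()
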