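"""Logarithmic trajectory fits, hemispheric F-test, asymptote extrapolation."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from gratio_dev import reference
from gratio_dev.roi import TABLE_COLUMNS
from gratio_dev.trajectories import (DegenerateDesignError, asymptote,
                                     fit_all_regions, fit_log_curve,
                                     hemispheric_f_test, round_half_up)
from conftest import STUDY_AGES


class TestFitLogCurve:
    def test_noiseless_recovery(self):
        ages = np.array([100.0, 500.0, 1000.0])
        g = -0.05 * np.log(ages) + 1.2
        fit = fit_log_curve(ages, g)
        assert fit.alpha == pytest.approx(-0.05, abs=1e-12)
        assert fit.intercept == pytest.approx(1.2, abs=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-24)

    def test_two_points_interpolate(self):
        fit = fit_log_curve([100.0, 1000.0], [0.9, 0.8])
        assert fit.rss == pytest.approx(0.0, abs=1e-24)
        assert fit.predict(100.0) == pytest.approx(0.9)

    def test_identical_ages_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            fit_log_curve([500.0, 500.0, 500.0], [0.8, 0.9, 0.85])

    def test_nonpositive_age_rejected(self):
        with pytest.raises(ValueError):
            fit_log_curve([0.0, 100.0], [0.9, 0.8])

    def test_matches_generic_minimizer(self, rng):
        """Closed-form OLS equals a numerically minimized least-squares fit."""
        for _ in range(5):
            ages = rng.uniform(80, 3000, 15)
            g = rng.normal(0.85, 0.05, 15)
            fit = fit_log_curve(ages, g)

            def sse(p):
                return np.sum((g - (p[0] * np.log(ages) + p[1])) ** 2)

            res = minimize(sse, x0=[0.0, 0.8], method="Nelder-Mead",
                           options={"xatol": 1e-12, "fatol": 1e-14,
                                    "maxiter": 10000})
            assert fit.alpha == pytest.approx(res.x[0], abs=1e-6)
            assert fit.rss == pytest.approx(res.fun, abs=1e-10)


class TestAsymptote:
    @pytest.mark.parametrize("region,expected", [
        ("Frontal WM", 0.77), ("Optic Radiation", 0.71), ("Cerebellar WM", 0.9),
    ])
    def test_published_left_fits_reproduce_reported_values(self, region, expected):
        fits = {f.region: f for f in reference.published_fits()
                if f.hemisphere == "left"}
        from gratio_dev.trajectories import LogCurveFit
        f = fits[region]
        fit = LogCurveFit(alpha=f.alpha, intercept=f.intercept, rss=0.0, n=18)
        assert asymptote(fit).rounded == pytest.approx(expected)

    def test_flat_curve_asymptote_is_intercept(self):
        from gratio_dev.trajectories import LogCurveFit
        fit = LogCurveFit(alpha=0.0, intercept=0.83, rss=0.0, n=18)
        assert asymptote(fit, 10.0).value == pytest.approx(0.83)
        assert asymptote(fit, 10000.0).value == pytest.approx(0.83)


def test_round_half_up_ties_away_from_zero():
    assert round_half_up(0.775, 2) == 0.78
    assert round_half_up(0.735, 2) == 0.74
    assert round_half_up(0.73, 2) == 0.73


class TestHemisphericFTest:
    def test_identical_hemispheres_give_zero_f(self):
        ages = np.array(STUDY_AGES, dtype=float)
        g = -0.04 * np.log(ages) + 1.1 + np.sin(ages / 300) * 0.01
        res = hemispheric_f_test(ages, g, ages, g)
        assert res.f_stat == pytest.approx(0.0, abs=1e-18)
        assert res.p_value == pytest.approx(1.0)
        assert res.df_num == 2 and res.df_den == 32

    def test_nestedness_on_random_data(self, rng):
        for _ in range(20):
            ages = rng.uniform(100, 2700, 12)
            gl = rng.normal(0.85, 0.03, 12)
            gr = rng.normal(0.84, 0.03, 12)
            res = hemispheric_f_test(ages, gl, ages, gr)
            assert res.single_fit.rss >= res.left_fit.rss + res.right_fit.rss - 1e-12
            assert res.f_stat >= 0.0
            assert 0.0 <= res.p_value <= 1.0

    def test_perfect_dual_fit_flags_infinite_f(self):
        ages = np.array([100.0, 500.0, 1000.0])
        x = np.log(ages)
        # each side exactly collinear (in ln age), but on different lines
        res = hemispheric_f_test(ages, -0.05 * x + 1.2, ages, -0.02 * x + 1.0)
        assert np.isinf(res.f_stat)
        assert res.p_value == 0.0
        assert res.degenerate

    def test_detects_true_hemispheric_difference(self):
        """Alpha gap of 0.02 at sd 0.005 is detected in most replicates."""
        ages = np.array(STUDY_AGES, dtype=float)
        x = np.log(ages)
        rng = np.random.default_rng(11)
        hits = 0
        reps = 200
        for _ in range(reps):
            gl = -0.046 * x + 1.19 + rng.normal(0, 0.005, x.size)
            gr = -0.026 * x + 1.19 + rng.normal(0, 0.005, x.size)
            if hemispheric_f_test(ages, gl, ages, gr).p_value < 0.05:
                hits += 1
        assert hits / reps > 0.5


def _region_table_from_published() -> pd.DataFrame:
    """Exact per-subject g means synthesized from the published equations."""
    rows = []
    ages = np.array(STUDY_AGES, dtype=float)
    for f in reference.published_fits():
        for i, age in enumerate(ages):
            rows.append({"subject_id": f"sub-{i:02d}", "age_days": age,
                         "region": f.region, "hemisphere": f.hemisphere,
                         "parameter": "g", "mean": f.predict(age),
                         "sd": 0.0, "n_voxels": 100})
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


class TestFitAllRegions:
    def test_round_trip_recovers_published_coefficients(self):
        table = _region_table_from_published()
        res = fit_all_regions(table)
        published = {(f.region, f.hemisphere): f for f in reference.published_fits()}
        assert len(res.fits) == 20
        for _, row in res.fits.iterrows():
            f = published[(row["region"], row["hemisphere"])]
            assert row["alpha"] == pytest.approx(f.alpha, abs=1e-9)
            assert row["intercept"] == pytest.approx(f.intercept, abs=1e-9)

    def test_constant_g_gives_zero_slope(self):
        rows = [{"subject_id": f"s{i}", "age_days": a, "region": "Genu CC",
                 "hemisphere": "midline", "parameter": "g", "mean": 0.8,
                 "sd": 0.0, "n_voxels": 10}
                for i, a in enumerate([100.0, 500.0, 2000.0])]
        res = fit_all_regions(pd.DataFrame(rows, columns=TABLE_COLUMNS))
        assert res.fits.iloc[0]["alpha"] == pytest.approx(0.0, abs=1e-15)
        assert res.asymptotes.iloc[0]["asymptote"] == pytest.approx(0.8)

    def test_underpopulated_region_skipped(self, caplog):
        table = _region_table_from_published()
        extra = table.iloc[:2].copy()
        extra["region"] = "Tiny"
        extra["hemisphere"] = "midline"
        res = fit_all_regions(pd.concat([table, extra], ignore_index=True))
        assert "Tiny" not in set(res.fits["region"])

    def test_one_asymptote_row_per_fit(self, small_cohort):
        from gratio_dev.gratio import compute_gratio_maps
        from gratio_dev.roi import merge_hemispheres, summarize_subject
        frames = []
        for subj in small_cohort.subjects:
            pm = small_cohort.maps[subj.subject_id]
            gm = compute_gratio_maps(pm)
            frames.append(summarize_subject(subj.subject_id, subj.age_days,
                                            {"g": gm.g}, small_cohort.labels,
                                            gm.defined_mask, small_cohort.regions))
        table = merge_hemispheres(pd.concat(frames, ignore_index=True))
        res = fit_all_regions(table)
        assert len(res.asymptotes) == len(res.fits)
        # every bilateral region contributes a left and a right row
        bilateral = res.fits[res.fits["hemisphere"].isin(["left", "right"])]
        counts = bilateral.groupby("region")["hemisphere"].nunique()
        assert (counts == 2).all()
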