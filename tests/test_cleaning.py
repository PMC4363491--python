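"""Assay cleaning: plate QC, zero removal, and the REML residualizer."""

import numpy as np
import pandas as pd
import pytest

from serogx import ANALYTES
from serogx.cleaning import (
    clean_serology,
    detect_outlier_plates,
    drop_failed_assays,
    reml_criterion,
    residualize,
)
from serogx.simulate import CohortConfig, generate_cohort


def _toy_frames(y, plate, storage):
    ids = [f"S{i}" for i in range(len(y))]
    log2_df = pd.DataFrame({"subject_id": ids, "CRP": y})
    subjects = pd.DataFrame(
        {"subject_id": ids, "plate": plate, "storage_years": storage})
    return log2_df, subjects


class TestOutlierPlates:
    def test_shifted_plate_is_the_only_flag(self):
        cfg = CohortConfig.default(seed=2)
        cfg.outlier_plate = 7
        cfg.outlier_shift = 3.0
        subjects, assays = generate_cohort(cfg)
        rep = detect_outlier_plates(assays, subjects)
        assert rep.flagged == [7]

    def test_clean_cohort_has_no_flags(self):
        subjects, assays = generate_cohort(CohortConfig.default(seed=3))
        rep = detect_outlier_plates(assays, subjects)
        assert rep.flagged == []

    def test_single_plate_returns_empty(self):
        cfg = CohortConfig.null(seed=1, group_size=20, n_plates=1)
        subjects, assays = generate_cohort(cfg)
        rep = detect_outlier_plates(assays, subjects)
        assert rep.flagged == []

    def test_tiny_plate_skipped_not_flagged(self):
        cfg = CohortConfig.null(seed=2, group_size=30, n_plates=5)
        subjects, assays = generate_cohort(cfg)
        # a 2-observation plate is skipped even with wild values
        subjects.loc[:1, "plate"] = 99
        assays.loc[:1, list(ANALYTES)] *= 1000
        rep = detect_outlier_plates(assays, subjects)
        assert 99 not in rep.flagged
        assert any(p == 99 for p, _ in rep.skipped)


class TestDropFailedAssays:
    def test_zero_becomes_missing_others_kept(self):
        assays = pd.DataFrame({
            "subject_id": ["S1"], "TOXO": [1.2], "HSV1": [0.8],
            "CMV": [2.0], "HHV6": [1.0], "GLIADIN": [0.5], "CRP": [0.0]})
        log2_df, n_zero = drop_failed_assays(assays)
        assert np.isnan(log2_df.loc[0, "CRP"])
        assert n_zero["CRP"] == 1
        assert log2_df.loc[0, "TOXO"] == pytest.approx(np.log2(1.2))
        assert sum(n_zero.values()) == 1

    def test_no_zeros_identity(self):
        rng = np.random.default_rng(0)
        assays = pd.DataFrame(
            {"subject_id": [f"S{i}" for i in range(5)],
             **{a: rng.uniform(0.1, 3, 5) for a in ANALYTES}})
        log2_df, n_zero = drop_failed_assays(assays)
        assert all(v == 0 for v in n_zero.values())
        for a in ANALYTES:
            np.testing.assert_allclose(log2_df[a], np.log2(assays[a]))

    def test_all_zero_subject_retained(self):
        assays = pd.DataFrame({
            "subject_id": ["S1"], **{a: [0.0] for a in ANALYTES}})
        log2_df, _ = drop_failed_assays(assays)
        assert len(log2_df) == 1
        assert log2_df[list(ANALYTES)].isna().all().all()


class TestResidualize:
    def test_blup_shrinkage_closed_form(self):
        """Balanced two-plate toy: the plate BLUP equals
        n*s2u/(n*s2u+s2e) times the plate-mean deviation.  Two plates fall
        back to fixed dummies, so use three and check the formula on each."""
        rng = np.random.default_rng(1)
        n_per = 50
        means = np.array([0.0, 2.0, -1.0])
        plate = np.repeat([1, 2, 3], n_per)
        storage = rng.uniform(0, 5, plate.size)
        y = means[plate - 1] + rng.normal(0, 1, plate.size)
        log2_df, subjects = _toy_frames(y, plate, storage)
        res, fit = residualize(log2_df, subjects, "CRP")
        assert fit.method == "reml"
        shrink = n_per * fit.sigma2_u / (n_per * fit.sigma2_u + fit.sigma2_e)
        gls_resid = y - fit.beta[0] - fit.beta[1] * storage
        for p in (1, 2, 3):
            dev = gls_resid[plate == p].mean()
            assert fit.blups[p] == pytest.approx(shrink * dev, rel=1e-6)

    def test_reml_matches_dense_grid_oracle(self):
        """The 1-D profiled optimum agrees with a brute-force grid search
        over the variance ratio evaluated through dense V matrices."""
        rng = np.random.default_rng(2)
        plate = np.repeat(np.arange(1, 9), 20)
        storage = rng.uniform(1, 15, plate.size)
        u = rng.normal(0, 0.7, 8)
        y = 0.5 + 0.05 * storage + u[plate - 1] + rng.normal(0, 1, plate.size)
        log2_df, subjects = _toy_frames(y, plate, storage)
        res, fit = residualize(log2_df, subjects, "CRP")

        X = np.column_stack([np.ones_like(y), storage])
        Z = (plate[:, None] == np.arange(1, 9)[None, :]).astype(float)
        n, p = X.shape

        def dense_crit(lam):
            V = np.eye(n) + lam * Z @ Z.T
            Vi = np.linalg.inv(V)
            XtViX = X.T @ Vi @ X
            beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
            r = y - X @ beta
            sigma2 = (r @ Vi @ r) / (n - p)
            return ((n - p) * np.log(sigma2)
                    + np.linalg.slogdet(V)[1]
                    + np.linalg.slogdet(XtViX)[1])

        lams = np.exp(np.linspace(-10, 4, 3000))
        crits = np.array([dense_crit(l) for l in lams])
        assert crits.min() >= fit.neg2_reml - 1e-6
        assert abs(dense_crit(fit.lam) - crits.min()) < 1e-6

    def test_reml_matches_statsmodels_mixedlm(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        plate = np.repeat(np.arange(1, 11), 15)
        storage = rng.uniform(0, 12, plate.size)
        y = 1 + 0.08 * storage + rng.normal(0, 0.9, 10)[plate - 1] \
            + rng.normal(0, 1, plate.size)
        log2_df, subjects = _toy_frames(y, plate, storage)
        _, fit = residualize(log2_df, subjects, "CRP")
        mf = sm.MixedLM(
            y, np.column_stack([np.ones_like(y), storage]), groups=plate
        ).fit(reml=True)
        assert fit.beta == pytest.approx(np.asarray(mf.fe_params), abs=1e-4)
        assert fit.sigma2_e == pytest.approx(mf.scale, rel=1e-3)
        assert fit.sigma2_u == pytest.approx(
            float(np.asarray(mf.cov_re)[0, 0]), rel=1e-3, abs=1e-5)

    def test_no_plate_effect_reduces_to_ols(self):
        rng = np.random.default_rng(4)
        plate = np.repeat(np.arange(1, 7), 40)
        storage = rng.uniform(0, 10, plate.size)
        y = 0.3 + 0.1 * storage + rng.normal(0, 1, plate.size)  # no plate term
        log2_df, subjects = _toy_frames(y, plate, storage)
        res, fit = residualize(log2_df, subjects, "CRP")
        X = np.column_stack([np.ones_like(y), storage])
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        ols_resid = y - X @ beta_ols
        if fit.sigma2_u < 1e-4:
            np.testing.assert_allclose(res.to_numpy(), ols_resid, atol=1e-3)

    def test_parameter_recovery_at_scale(self):
        """Generative slope and variance ratio recovered on a full-size
        cohort with strong plate effects."""
        cfg = CohortConfig.null(seed=5, group_size=372, n_plates=32)
        cfg.plate_sd = 1.0
        cfg.storage_slope = 0.05
        subjects, assays = generate_cohort(cfg)
        log2_df, _ = drop_failed_assays(assays)
        _, fit = residualize(log2_df, subjects, "CRP")
        se_slope_rough = 1.0 / (np.std(subjects["storage_years"])
                                * np.sqrt(len(subjects)))
        assert fit.beta[1] == pytest.approx(0.05, abs=2 * se_slope_rough)
        assert fit.sigma2_u / fit.sigma2_e == pytest.approx(1.0, rel=0.6)

    def test_two_plates_falls_back_to_dummies(self):
        rng = np.random.default_rng(6)
        plate = np.repeat([1, 2], 30)
        y = rng.normal(0, 1, 60) + (plate == 2) * 1.0
        log2_df, subjects = _toy_frames(y, plate, rng.uniform(0, 5, 60))
        res, fit = residualize(log2_df, subjects, "CRP")
        assert fit.method == "fixed_dummies"
        assert abs(res.mean()) < 1e-8

    def test_too_few_plates_rejected(self):
        y = np.arange(4.0)
        log2_df, subjects = _toy_frames(y, np.ones(4, dtype=int), np.zeros(4))
        with pytest.raises(ValueError, match="plates"):
            residualize(log2_df, subjects, "CRP")


class TestResidualProperties:
    def test_mean_zero_and_shift_invariance(self):
        rng = np.random.default_rng(7)
        plate = np.repeat(np.arange(1, 6), 30)
        storage = rng.uniform(0, 10, plate.size)
        y = rng.normal(0, 1, plate.size) + rng.normal(0, 0.5, 5)[plate - 1]
        log2_df, subjects = _toy_frames(y, plate, storage)
        res1, _ = residualize(log2_df, subjects, "CRP")
        assert abs(res1.mean()) < 1e-8
        log2_df2 = log2_df.copy()
        log2_df2["CRP"] = log2_df2["CRP"] + 7.5
        res2, _ = residualize(log2_df2, subjects, "CRP")
        np.testing.assert_allclose(res1.to_numpy(), res2.to_numpy(), atol=1e-7)


class TestCleanSerology:
    def test_failed_plate_accounting(self):
        cfg = CohortConfig.with_failed_plate(seed=1)
        subjects, assays = generate_cohort(cfg)
        assert len(subjects) == 2660
        result = clean_serology(subjects, assays)
        assert result.outlier_report.flagged == [cfg.outlier_plate]
        assert len(result.subjects) == 2587
        assert result.n_excluded_plate == 73
        report = result.report_frame()
        assert set(report["analyte"]) == set(ANALYTES)
        assert (report["method"] == "reml").all()
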