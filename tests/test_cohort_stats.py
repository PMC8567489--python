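"""Cohort generator and the precision / rank / PLS / ROC statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from cortbs.cohort import CohortSpec, GroupSpec, generate_cohort
from cortbs.statsdisc import (
    ConfusionMatrix,
    DiscriminationModel,
    PLSModel,
    compare_auc,
    cross_validated_pls,
    odds_ratio,
    pls_fit,
    roc_metrics,
    short_term_precision,
    spa_select,
    spearman_rho,
    wilcoxon_rank_sum,
)


class TestCohort:
    def test_group_means_match_spec_within_3se(self):
        """Large cohort reproduces the configured Fx attenuation mean."""
        spec = CohortSpec(n_fx=10_000, n_nfx=10_000, n_vertebral=6000, n_other=6000)
        c = generate_cohort(spec, seed=0)
        fx = c[c.group == "Fx"]
        se = 0.40 / np.sqrt(len(fx))
        assert abs(fx["Ct.alpha0"].mean() - 2.34) < 3 * se
        se_f = 0.06 / np.sqrt(len(fx))
        assert abs(fx["Ct.alphaf"].mean() - 0.11) < 3 * se_f

    def test_bmi_consistent_with_height_weight(self):
        c = generate_cohort(seed=1)
        bmi = c["Weight"] / (c["Height"] / 100) ** 2
        assert np.allclose(bmi, c["BMI"])

    def test_default_composition_and_subtypes(self):
        c = generate_cohort(seed=2)
        assert len(c) == 55
        assert (c.group == "Fx").sum() == 29
        assert c["fracture_vertebral"].sum() == 18
        assert c["fracture_other"].sum() == 21
        # every flagged subject is in the Fx group; every Fx subject has >= 1
        fx = c[c.group == "Fx"]
        assert (fx["fracture_vertebral"] | fx["fracture_other"]).all()
        nfx = c[c.group == "nFx"]
        assert not (nfx["fracture_vertebral"] | nfx["fracture_other"]).any()

    def test_spine_tscore_missingness_flagged(self):
        c = generate_cohort(seed=3)
        miss = c["T_score_Spine_missing"]
        assert miss.sum() > 0
        assert c.loc[miss, "T_score_Spine"].isna().all()
        assert c.loc[~miss, "T_score_Spine"].notna().all()

    def test_seed_determinism(self):
        a = generate_cohort(seed=4)
        b = generate_cohort(seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_incompatible_subtype_counts_rejected(self):
        with pytest.raises(ValueError, match="subtype"):
            generate_cohort(CohortSpec(n_vertebral=5, n_other=5), seed=0)


class TestPrecision:
    def test_identical_repeats_zero(self):
        pr = short_term_precision(np.tile([[3.0, 3.0, 3.0]], (4, 1)))
        assert pr.absolute == 0.0 and pr.relative_pct == 0.0

    def test_matches_brute_force_per_subject_sds(self):
        rng = np.random.default_rng(0)
        reps = 30 + rng.normal(0, 2.5, size=(3, 10))
        pr = short_term_precision(reps)
        sd = reps.std(axis=1, ddof=1)
        m = reps.mean(axis=1)
        assert pr.absolute == pytest.approx(np.sqrt(np.mean(sd**2)), rel=1e-12)
        assert pr.relative_pct == pytest.approx(
            100 * np.sqrt(np.mean((sd / m) ** 2)), rel=1e-12
        )

    def test_programmed_sd_recovered(self):
        """3 subjects x 10 repeats with SD 2.5 around ~30 -> ~2.5 (8.3%)."""
        rng = np.random.default_rng(5)
        reps = np.array([[m + rng.normal(0, 2.5) for _ in range(10)] for m in (28, 30, 32)])
        pr = short_term_precision(reps)
        assert pr.absolute == pytest.approx(2.5, rel=0.35)
        assert pr.relative_pct == pytest.approx(8.3, rel=0.40)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        reps = 30 + rng.normal(0, 2.0, size=(3, 10))
        a = short_term_precision(reps)
        b = short_term_precision(reps * 4.0)
        assert b.absolute == pytest.approx(4.0 * a.absolute, rel=1e-12)
        assert b.relative_pct == pytest.approx(a.relative_pct, rel=1e-12)

    def test_zero_mean_flags_relative(self):
        reps = np.array([[-1.0, 1.0], [2.0, 3.0]])
        pr = short_term_precision(reps)
        assert not pr.relative_defined

    def test_format_matches_report_style(self):
        pr = short_term_precision(np.array([[29.0, 31.0], [30.0, 34.0]]))
        assert "(" in str(pr) and ")" in str(pr)


class TestRankStatistics:
    def test_wilcoxon_identical_samples_p1(self):
        assert wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])[1] == 1.0

    def test_wilcoxon_exact_small_sample(self):
        """{1,2,3} vs {4,5,6}: only 1 of C(6,3)=20 rank splits as extreme
        per side -> two-sided exact p = 2/20 = 0.1."""
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, rel=1e-9)

    def test_wilcoxon_constant_data(self):
        assert wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0])[1] == 1.0

    def test_spearman_monotone_is_one(self):
        rho, _ = spearman_rho([1, 2, 3, 5, 9], [10, 20, 21, 40, 80])
        assert rho == pytest.approx(1.0, rel=1e-12)

    def test_spearman_matches_brute_force_ranks(self):
        x = [3.1, 1.2, 5.5, 2.2, 4.0, 0.7]
        y = [9.0, 2.0, 8.0, 3.5, 7.0, 1.0]
        rho, _ = spearman_rho(x, y)
        rx, ry = st.rankdata(x), st.rankdata(y)
        brute = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(brute, rel=1e-12)

    def test_spearman_pairwise_complete(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0]
        y = [2.0, 1.0, 3.0, 5.0, 4.0, 7.0, 6.0, 9.0, 8.0, 11.0, 10.0]
        rho, p = spearman_rho(x, y)
        assert np.isfinite(rho) and 0 <= p <= 1

    def test_spearman_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="variance"):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPLS:
    def test_single_column_proportional_r2_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        y = 2.5 * X[:, 1]
        m = pls_fit(X, y, ncomp=1)
        assert m.score(X, y) > 0.85  # one component captures the target

    def test_full_rank_equals_ols(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0]) + 0.1 * rng.normal(size=30)
        m = pls_fit(X, y, ncomp=4)
        ols = np.linalg.lstsq(np.column_stack([X, np.ones(30)]), y, rcond=None)[0]
        assert np.allclose(m.coef_, ols[:4], atol=1e-8)

    def test_matches_sklearn_nipals(self):
        """Independent route: sklearn PLSRegression on the same data."""
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 6))
        y = X[:, 0] - X[:, 3] + 0.2 * rng.normal(size=25)
        ours = pls_fit(X, y, ncomp=3)
        sk = PLSRegression(n_components=3, scale=True).fit(X, y)
        assert np.allclose(ours.coef_, sk.coef_.ravel(), atol=1e-8)

    def test_score_vectors_orthogonal(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 5))
        y = rng.normal(size=40)
        m = pls_fit(X, y, ncomp=3)
        G = m.x_scores_.T @ m.x_scores_
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()

    def test_zero_variance_column_named(self):
        X = np.ones((10, 2))
        X[:, 0] = np.arange(10)
        with pytest.raises(ValueError, match="constant_col"):
            pls_fit(X, np.arange(10.0), column_names=["ok", "constant_col"])


class TestCrossValidation:
    def test_loocv_prediction_count(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(18, 4))
        y = rng.normal(size=18)
        preds, rho, rmse = cross_validated_pls(X, y, ncomp=2, scheme="loocv")
        assert preds.shape == (18,)
        assert np.isfinite(rho) and rmse > 0

    def test_no_leakage_of_held_out_label(self):
        """Flipping a subject's label leaves its own out-of-fold score
        untouched (fold 5's model never sees subject 5)."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(16, 4))
        y = np.repeat([1.0, -1.0], 8)
        p1, _, _ = cross_validated_pls(X, y, ncomp=2, scheme="loocv")
        y2 = y.copy()
        y2[5] = -y2[5]
        p2, _, _ = cross_validated_pls(X, y2, ncomp=2, scheme="loocv")
        assert p2[5] == pytest.approx(p1[5], rel=1e-12)
        # other folds do see the changed label, so at least some move
        assert not np.allclose(np.delete(p1, 5), np.delete(p2, 5))

    def test_kfold_stratified_and_seeded(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 4))
        y = np.repeat([1.0, -1.0], [18, 12])
        p1, _, _ = cross_validated_pls(X, y, ncomp=2, scheme="kfold", seed=7)
        p2, _, _ = cross_validated_pls(X, y, ncomp=2, scheme="kfold", seed=7)
        assert np.array_equal(p1, p2)

    def test_degenerate_fold_rejected(self):
        X = np.random.default_rng(3).normal(size=(5, 2))
        y = np.array([1.0, -1.0, -1.0, -1.0, -1.0])
        with pytest.raises(ValueError, match="fold"):
            cross_validated_pls(X, y, ncomp=1, scheme="loocv")

    def test_regression_mode_outputs(self):
        """Continuous target: rho and RMSE against the measured values."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 5))
        y = X[:, 0] + 0.3 * rng.normal(size=40)
        _, rho, rmse = cross_validated_pls(X, y, ncomp=2, scheme="kfold", seed=0)
        assert rho > 0.7
        assert rmse < 1.0


class TestSPA:
    def test_informative_variable_selected(self):
        hits = 0
        for s in range(5):
            rng = np.random.default_rng(s)
            X = rng.normal(size=(50, 10))
            y = np.repeat([1.0, -1.0], 25)
            X[:, 3] += 0.75 * y  # standardized separation 1.5
            sel = spa_select(X, y, n_mc=300, seed=s)
            hits += "x3" in sel
        assert hits >= 4

    def test_all_noise_rarely_selects(self):
        n_sel = 0
        for s in range(5):
            rng = np.random.default_rng(100 + s)
            X = rng.normal(size=(50, 10))
            y = np.repeat([1.0, -1.0], 25)
            with np.errstate(all="ignore"):
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    sel = spa_select(X, y, n_mc=300, seed=s)
            n_sel += len(sel)
        # expected false selections: ~0.05 per variable -> ~0.5 per run
        assert n_sel <= 10

    def test_too_few_variables_rejected(self):
        with pytest.raises(ValueError, match="2"):
            spa_select(np.ones((10, 1)), np.repeat([1.0, -1.0], 5))


class TestROC:
    def test_perfect_separation(self):
        scores = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        labels = np.array([0, 0, 0, 1, 1, 1], bool)
        roc, cm = roc_metrics(scores, labels)
        assert roc.auc == 1.0
        assert roc.sensitivity == 1.0 and roc.specificity == 1.0
        assert cm.tp == 3 and cm.tn == 3 and cm.fn == 0 and cm.fp == 0

    def test_auc_equals_pairwise_count_with_ties(self):
        rng = np.random.default_rng(0)
        scores = np.round(rng.normal(size=12), 1)  # provoke ties
        labels = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0], bool)
        roc, _ = roc_metrics(scores, labels)
        pos, neg = scores[labels], scores[~labels]
        brute = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg) / (
            pos.size * neg.size
        )
        assert roc.auc == pytest.approx(brute, rel=1e-12)

    def test_auc_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=20)
        labels = rng.random(20) > 0.4
        a1 = roc_metrics(scores, labels)[0].auc
        a2 = roc_metrics(np.exp(3 * scores), labels)[0].auc
        assert a1 == pytest.approx(a2, rel=1e-12)

    def test_negation_and_label_swap_symmetry(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=15)
        labels = rng.random(15) > 0.5
        a = roc_metrics(scores, labels)[0].auc
        b = roc_metrics(-scores, ~labels)[0].auc
        assert a == pytest.approx(b, rel=1e-12)

    def test_accuracy_consistent_with_confusion(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=30)
        labels = rng.random(30) > 0.5
        roc, cm = roc_metrics(scores, labels)
        assert roc.accuracy == pytest.approx(cm.accuracy, rel=1e-12)
        assert cm.tp + cm.fn == labels.sum()
        assert cm.tn + cm.fp == (~labels).sum()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            roc_metrics(np.arange(5.0), np.ones(5, bool))


class TestOddsRatio:
    def test_cross_product_17(self):
        assert odds_ratio(ConfusionMatrix(tp=7, fn=7, tn=34, fp=2))[0] == pytest.approx(17.0)

    def test_symmetric_table_is_one(self):
        assert odds_ratio(ConfusionMatrix(tp=5, fn=5, tn=5, fp=5))[0] == 1.0

    def test_cross_product_8_25(self):
        assert odds_ratio(ConfusionMatrix(tp=6, fn=8, tn=33, fp=3))[0] == pytest.approx(8.25)

    def test_zero_cell_haldane(self):
        orr, (lo, hi) = odds_ratio(ConfusionMatrix(tp=5, fn=0, tn=5, fp=5))
        assert np.isfinite(orr) and lo > 0 and hi > orr

    def test_woolf_ci_contains_point(self):
        orr, (lo, hi) = odds_ratio(ConfusionMatrix(tp=10, fn=5, tn=20, fp=4))
        assert lo < orr < hi


class TestCompareAUC:
    def test_identical_rocs_z_zero(self):
        r, _ = roc_metrics(np.arange(10.0), np.arange(10) >= 5)
        z, p = compare_auc(r, r)
        assert z == 0.0 and p == 1.0

    def test_sign_matches_auc_difference(self):
        rng = np.random.default_rng(0)
        labels = np.repeat([True, False], 15)
        good = np.where(labels, 1.0, 0.0) + 0.5 * rng.normal(size=30)
        bad = rng.normal(size=30)
        r1, _ = roc_metrics(good, labels)
        r2, _ = roc_metrics(bad, labels)
        z, p = compare_auc(r1, r2)
        assert z > 0 and p < 0.5

    def test_invalid_correlation_rejected(self):
        r, _ = roc_metrics(np.arange(10.0), np.arange(10) >= 5)
        with pytest.raises(ValueError):
            compare_auc(r, r, r=1.5)


class TestDiscriminationModel:
    def test_null_cohort_auc_near_half(self):
        spec = CohortSpec(fx=GroupSpec.null(), nfx=GroupSpec.null())
        aucs = []
        for s in range(10):
            c = generate_cohort(spec, seed=s)
            res = DiscriminationModel.from_cohort(c, endpoint="all",
                                                  features="cortbs").fit(seed=s)
            aucs.append(res.roc.auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.12)

    def test_effectful_cohort_beats_chance(self):
        aucs = []
        for s in range(6):
            c = generate_cohort(seed=s)
            res = DiscriminationModel.from_cohort(c, endpoint="all",
                                                  features="attenuation").fit(seed=s)
            aucs.append(res.roc.auc)
        assert 0.6 <= np.median(aucs) <= 0.95

    def test_vertebral_endpoint_composition(self):
        c = generate_cohort(seed=1)
        dm = DiscriminationModel.from_cohort(c, endpoint="vertebral", features="cortbs")
        assert dm.y.sum() == 18
        assert (~dm.y).sum() == 26

    def test_listwise_deletion_of_missing(self):
        c = generate_cohort(seed=2)
        dm = DiscriminationModel.from_cohort(c, endpoint="all", features="dxa")
        assert dm.n_dropped == c["T_score_Spine"].isna().sum()

    def test_summary_row_table_shape(self):
        c = generate_cohort(seed=3)
        res = DiscriminationModel.from_cohort(c, endpoint="all",
                                              features="attenuation").fit(seed=3)
        row = res.summary_row()
        for key in ("sensitivity", "specificity", "AUC", "SE", "accuracy",
                    "OR", "OR_CI", "variables"):
            assert key in row
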