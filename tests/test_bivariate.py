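"""Bivariate random-effects model: fits, SROC, heterogeneity, comparisons."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.special import expit, logit
from scipy.stats import kstest

from serodta.bivariate import (
    BivariateFit,
    FitError,
    bivariate_i2,
    compare_groups,
    detect_outliers,
    fit_bivariate,
    higgins_i2,
    pooled_summaries,
    refit_without_outliers,
    sroc_auc_quad,
    sroc_curve_and_auc,
    subgroup_analysis,
    subgroup_indicator,
    threshold_effect_proportion,
)
from serodta.dta_core import Study2x2Record, study_accuracy
from serodta.synthetic import MetaSimConfig

from conftest import simulate_accuracies


def make_fit(mu_sens=0.8, mu_spec=1.5, tau2_sens=0.3, tau2_spec=0.2, rho=-0.6,
             cov_scale=1e-3):
    return BivariateFit(
        mu_sens_logit=mu_sens, mu_spec_logit=mu_spec,
        tau2_sens=tau2_sens, tau2_spec=tau2_spec, rho=rho,
        fixed_effect_cov=np.eye(2) * cov_scale, loglik=0.0,
        n_studies=10, converged=True,
    )


def he4_like_config(seed, **kw):
    base = dict(
        biomarker="B", n_studies=30, true_sens=0.73, true_spec=0.83,
        tau2_sens=0.3, tau2_spec=0.3, rho=-0.3,
        case_size_range=(200, 200), control_size_range=(200, 200), seed=seed,
    )
    base.update(kw)
    return MetaSimConfig(**base)


class TestFit:
    def test_homogeneous_copies_collapse_to_fixed_effect(self):
        acc = study_accuracy(
            Study2x2Record(study_id="s", biomarker="B", tp=60, fp=15, fn=40, tn=85)
        )
        fit = fit_bivariate([acc] * 10)
        assert fit.tau2_sens == 0.0
        assert fit.tau2_spec == 0.0
        assert expit(fit.mu_sens_logit) == pytest.approx(0.600, abs=1e-6)
        assert expit(fit.mu_spec_logit) == pytest.approx(0.850, abs=1e-6)
        assert fit.converged

    def test_below_minimum_studies_rejected(self):
        acc = study_accuracy(
            Study2x2Record(study_id="s", biomarker="B", tp=60, fp=15, fn=40, tn=85)
        )
        with pytest.raises(FitError, match="at least 4"):
            fit_bivariate([acc, acc])

    def test_zero_tau_limit_is_inverse_variance_mean(self):
        """With no heterogeneity the GLS mean must equal the closed-form
        inverse-variance weighted mean, component by component."""
        accs = simulate_accuracies(he4_like_config(seed=21, tau2_sens=0.0,
                                                   tau2_spec=0.0, rho=0.0))
        fit = fit_bivariate(accs)
        if fit.tau2_sens == 0.0 and fit.tau2_spec == 0.0:
            for comp, (mu_hat) in zip(
                ("sens", "spec"), (fit.mu_sens_logit, fit.mu_spec_logit)
            ):
                y = np.array([getattr(a, f"logit_{comp}") for a in accs])
                w = np.array([1.0 / getattr(a, f"se_logit_{comp}") ** 2 for a in accs])
                assert mu_hat == pytest.approx(float((w * y).sum() / w.sum()), abs=1e-6)
        else:  # tiny estimated heterogeneity: still near the weighted mean
            y = np.array([a.logit_sens for a in accs])
            w = np.array([1.0 / a.se_logit_sens**2 for a in accs])
            assert fit.mu_sens_logit == pytest.approx((w * y).sum() / w.sum(), abs=0.02)

    def test_permutation_invariance(self, rng):
        accs = simulate_accuracies(he4_like_config(seed=22))
        fit_a = fit_bivariate(accs)
        shuffled = [accs[i] for i in rng.permutation(len(accs))]
        fit_b = fit_bivariate(shuffled)
        assert fit_b.mu_sens_logit == pytest.approx(fit_a.mu_sens_logit, abs=1e-8)
        assert fit_b.tau2_sens == pytest.approx(fit_a.tau2_sens, abs=1e-8)
        assert fit_b.rho == pytest.approx(fit_a.rho, abs=1e-6)


class TestPooledSummaries:
    def test_symmetric_fit_gives_uninformative_summaries(self):
        fit = make_fit(mu_sens=0.0, mu_spec=0.0, rho=0.0)
        pooled = pooled_summaries(fit)
        assert pooled.pooled_sens == pytest.approx(0.5)
        assert pooled.pooled_spec == pytest.approx(0.5)
        assert pooled.pplr == pytest.approx(1.0)
        assert pooled.pnlr == pytest.approx(1.0)
        assert pooled.pdor == pytest.approx(1.0)

    def test_published_row_arithmetic(self):
        fit = make_fit(mu_sens=float(logit(0.73)), mu_spec=float(logit(0.83)))
        pooled = pooled_summaries(fit)
        assert pooled.pooled_sens == pytest.approx(0.73)
        assert pooled.pooled_spec == pytest.approx(0.83)
        assert round(pooled.pplr, 1) == 4.3

    def test_monte_carlo_dor_ci_matches_delta_method(self):
        """On a well-conditioned fit the MC percentile CI for the DOR must
        agree with the log-scale delta-method interval to ~2% relative."""
        cov = np.array([[0.004, 0.001], [0.001, 0.003]])
        fit = make_fit(mu_sens=1.0, mu_spec=1.5, rho=-0.3)
        fit.fixed_effect_cov = cov
        pooled = pooled_summaries(fit, n_draws=400_000)
        # ln DOR = logit sens + logit spec → var = v11 + v22 + 2 v12
        ln_dor = fit.mu_sens_logit + fit.mu_spec_logit
        se = math.sqrt(cov[0, 0] + cov[1, 1] + 2 * cov[0, 1])
        z = 1.959963984540054
        lo, hi = math.exp(ln_dor - z * se), math.exp(ln_dor + z * se)
        assert pooled.pdor_ci[0] == pytest.approx(lo, rel=0.02)
        assert pooled.pdor_ci[1] == pytest.approx(hi, rel=0.02)

    def test_intervals_bracket_points(self):
        accs = simulate_accuracies(he4_like_config(seed=23))
        fit = fit_bivariate(accs)
        pooled = pooled_summaries(fit, accs)
        assert pooled.sens_ci[0] <= pooled.pooled_sens <= pooled.sens_ci[1]
        assert pooled.pplr_ci[0] <= pooled.pplr <= pooled.pplr_ci[1]
        assert pooled.pnlr_ci[0] <= pooled.pnlr <= pooled.pnlr_ci[1]
        assert pooled.pdor_ci[0] <= pooled.pdor <= pooled.pdor_ci[1]
        assert pooled.pplr > 1.0  # sens > 1 − spec here


class TestSROC:
    @pytest.mark.parametrize("sens", [0.5, 0.9])
    def test_constant_curve_integrates_to_its_level(self, sens):
        fit = make_fit(mu_sens=float(logit(sens)), tau2_sens=0.0, tau2_spec=0.0, rho=0.0)
        _, curve, auc = sroc_curve_and_auc(fit, grid_size=10001)
        assert np.all(curve == curve[0])
        assert auc == pytest.approx(sens, abs=1e-12)

    def test_trapezoid_matches_adaptive_quadrature(self):
        fit = make_fit()
        _, _, auc = sroc_curve_and_auc(fit, grid_size=10001)
        assert auc == pytest.approx(sroc_auc_quad(fit), abs=1e-4)

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError):
            sroc_curve_and_auc(make_fit(), grid_size=1)

    def test_curve_through_summary_point(self):
        fit = make_fit()
        fpr = np.array([1.0 - expit(fit.mu_spec_logit)])
        sens = float(expit(fit.mu_sens_logit))
        from serodta.bivariate import sroc_sens_at_fpr

        assert sroc_sens_at_fpr(fit, fpr)[0] == pytest.approx(sens, abs=1e-12)


class TestHeterogeneity:
    def test_no_heterogeneity_gives_zero_i2(self):
        accs = simulate_accuracies(he4_like_config(seed=24))
        fit = make_fit(tau2_sens=0.0, tau2_spec=0.0, rho=0.0)
        assert bivariate_i2(fit, accs) == 0.0

    def test_i2_increases_with_between_study_variance(self):
        accs = simulate_accuracies(he4_like_config(seed=24))
        values = []
        for scale in (0.05, 0.1, 0.3, 1.0, 3.0):
            fit = make_fit(tau2_sens=scale, tau2_spec=scale, rho=-0.3)
            values.append(bivariate_i2(fit, accs))
        assert all(b > a for a, b in zip(values, values[1:]))
        assert all(0.0 <= v <= 100.0 for v in values)

    def test_homogeneous_copies_have_negligible_i2(self):
        acc = study_accuracy(
            Study2x2Record(study_id="s", biomarker="B", tp=60, fp=15, fn=40, tn=85)
        )
        accs = [acc] * 10
        fit = fit_bivariate(accs)
        assert bivariate_i2(fit, accs) < 1.0
        assert higgins_i2(
            np.array([a.logit_sens for a in accs]),
            np.array([a.se_logit_sens**2 for a in accs]),
        ) == 0.0

    @pytest.mark.parametrize(
        "rho, expected",
        [(0.0, 0.0), (-1.0, 100.0), (0.5, 0.0), (-0.5, 25.0)],
    )
    def test_threshold_effect_definition(self, rho, expected):
        fit = make_fit(rho=rho)
        assert threshold_effect_proportion(fit) == pytest.approx(expected)


class TestOutliers:
    def test_planted_outlier_flagged(self):
        accs = simulate_accuracies(he4_like_config(seed=25, n_studies=20))
        shift = 5.0 * math.sqrt(0.3)
        planted = dataclasses.replace(
            accs[0], logit_sens=accs[0].logit_sens + shift, study_id="planted"
        )
        studies = [planted] + accs[1:]
        fit = fit_bivariate(studies)
        reports = {r.study_id: r for r in detect_outliers(fit, studies)}
        assert reports["planted"].flagged
        assert abs(reports["planted"].z_sens) > 2.0

    def test_false_flag_rate_near_nominal_under_null(self):
        """Exchangeable studies: each standardized component is ≈N(0,1), so
        the per-study flag rate should sit near 2·2·(1−Φ(2)) ≈ 9%."""
        n_flagged = n_total = 0
        for seed in range(30):
            accs = simulate_accuracies(he4_like_config(seed=400 + seed, n_studies=20))
            fit = fit_bivariate(accs)
            reports = detect_outliers(fit, accs)
            n_flagged += sum(r.flagged for r in reports)
            n_total += len(reports)
        rate = n_flagged / n_total
        assert 0.02 < rate < 0.16

    def test_boundary_residual_exactly_two_not_flagged(self):
        fit = make_fit(mu_sens=0.0, mu_spec=0.0, tau2_sens=1.0, tau2_spec=1.0,
                       rho=0.0)
        # within-variance 1 → b = r/2, sd(b) = sqrt(1/2), z = r/sqrt(2)
        r = 2.0 * math.sqrt(2.0)
        acc = dataclasses.replace(
            study_accuracy(
                Study2x2Record(study_id="s", biomarker="B", tp=50, fp=50, fn=50, tn=50)
            ),
            logit_sens=r, logit_spec=0.0, se_logit_sens=1.0, se_logit_spec=1.0,
        )
        report = detect_outliers(fit, [acc])[0]
        assert report.z_sens == 2.0
        assert not report.flagged

    def test_refit_without_outliers_drops_flagged(self):
        accs = simulate_accuracies(he4_like_config(seed=26, n_studies=20))
        shift = 6.0 * math.sqrt(0.3)
        planted = dataclasses.replace(
            accs[0], logit_sens=accs[0].logit_sens + shift, study_id="planted"
        )
        studies = [planted] + accs[1:]
        fit = fit_bivariate(studies)
        refit, kept, reports = refit_without_outliers(fit, studies)
        assert "planted" not in {a.study_id for a in kept}
        assert refit.n_studies == len(kept)


class TestCompareGroups:
    def test_identity_comparison(self):
        accs = simulate_accuracies(he4_like_config(seed=27, n_studies=15))
        res = compare_groups(accs + accs, [True] * 15 + [False] * 15)
        assert res.relative_sensitivity == pytest.approx(1.0, abs=1e-6)
        assert res.relative_specificity == pytest.approx(1.0, abs=1e-6)
        assert res.p_global > 0.9

    def test_too_small_group_rejected(self):
        accs = simulate_accuracies(he4_like_config(seed=27, n_studies=10))
        with pytest.raises(FitError, match="at least 4"):
            compare_groups(accs, [True] * 3 + [False] * 7)

    def test_planted_sensitivity_ratio_recovered(self):
        """True sens ratio 1.2 with equal spec: the relative-sensitivity CI
        should cover 1.2 in ≈95% of replicates and p_spec stay quiet."""
        covered = 0
        spec_p = []
        for seed in range(50):
            g1 = simulate_accuracies(
                he4_like_config(seed=800 + seed, true_sens=0.73 * 1.2, n_studies=25)
            )
            g0 = simulate_accuracies(
                he4_like_config(seed=900 + seed, true_sens=0.73, n_studies=25)
            )
            res = compare_groups(
                g1 + g0, [True] * 25 + [False] * 25, n_draws=4000, seed=seed
            )
            covered += res.rel_sens_ci[0] <= 1.2 <= res.rel_sens_ci[1]
            spec_p.append(res.p_spec)
        assert covered >= 43  # ≥86% over 50 replicates at nominal 95%
        assert np.mean(np.asarray(spec_p) < 0.05) < 0.15

    def test_global_p_uniform_under_label_permutation(self):
        """Permuting group labels of one dataset must leave the global test
        with approximately uniform p-values."""
        accs = simulate_accuracies(
            he4_like_config(seed=42, n_studies=50, tau2_sens=0.2, tau2_spec=0.2,
                            case_size_range=(40, 200), control_size_range=(40, 200))
        )
        rng = np.random.default_rng(7)
        pvals = []
        for rep in range(500):
            ind = np.zeros(50, dtype=bool)
            ind[rng.choice(50, 25, replace=False)] = True
            pvals.append(compare_groups(accs, ind, n_draws=200, seed=rep).p_global)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestSubgroups:
    def _records(self, seed, effect=0.0, n=30):
        cfg = he4_like_config(
            seed=seed, n_studies=n,
            case_size_range=(40, 200), control_size_range=(40, 200),
        )
        if effect:
            cfg.covariate_effects = {"late_majority": ("spec", effect)}
        from serodta.synthetic import simulate_dta_studies

        recs = simulate_dta_studies(cfg)
        accs = simulate_accuracies(cfg)
        return recs, accs

    def test_constant_covariate_rejected(self):
        recs, accs = self._records(seed=31)
        uniform = [dataclasses.replace(r, assay_method="CLIA") for r in recs]
        with pytest.raises(FitError, match="per level"):
            subgroup_analysis(uniform, accs, "assay_method")

    def test_exact_half_late_stage_is_early_level(self):
        recs, _ = self._records(seed=31)
        boundary = [dataclasses.replace(recs[0], pct_late_stage=0.5)]
        _, ind, _ = subgroup_indicator(boundary, "pct_late_stage")
        assert ind == [False]

    def test_planted_specificity_effect_detected(self):
        detected = null_hits = 0
        for seed in range(9):
            recs, accs = self._records(seed=600 + seed, effect=-1.0, n=31)
            res = subgroup_analysis(recs, accs, "pct_late_stage", seed=seed)
            detected += res.p_spec < 0.05
            recs0, accs0 = self._records(seed=700 + seed, effect=0.0, n=31)
            res0 = subgroup_analysis(recs0, accs0, "pct_late_stage", seed=seed)
            null_hits += res0.p_spec < 0.05
        assert detected >= 6  # majority of replicates at the planted effect size
        assert null_hits <= 3

    def test_unknown_covariate_rejected(self):
        recs, accs = self._records(seed=31)
        with pytest.raises(ValueError, match="unsupported"):
            subgroup_analysis(recs, accs, "language")
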