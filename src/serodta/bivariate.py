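"""Bivariate random-effects meta-analysis of sensitivity and specificity.

The model is the normal–normal approximation to the classic bivariate DTA
model: each study contributes the pair ``y_i = (logit sens_i, logit spec_i)``
with known (estimated) within-study variances and independent within-study
components; between studies the pair is bivariate normal with mean
``(mu_sens, mu_spec)`` and unstructured covariance

    T = [[tau1^2,            rho*tau1*tau2],
         [rho*tau1*tau2,     tau2^2      ]].

Between-study correlation ``rho`` < 0 (on the sens/spec scale) is the
signature of a threshold effect: studies with stricter positivity cutoffs
trade sensitivity for specificity.  Estimation is by restricted maximum
likelihood (REML) over the three covariance parameters with the fixed
effects profiled out by generalized least squares; maximum likelihood is
used where nested fixed-effect structures must be compared by a likelihood
ratio.

The fitted model yields pooled summaries (sensitivity, specificity,
likelihood ratios, DOR, all with 95% intervals), the summary ROC curve and
its area, a bivariate generalization of Higgins' I² heterogeneity index,
a threshold-effect proportion, empirical-Bayes outlier diagnostics, and
covariate comparisons via bivariate meta-regression with a 2-df global test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import chi2, norm

from .dta_core import StudyAccuracy, Z95

#: default seed for the parametric Monte Carlo used in interval propagation
MC_SEED = 20241019

#: minimum number of studies per bivariate fit
MIN_STUDIES = 4

_TAU2_FLOOR = 1e-8


class FitError(RuntimeError):
    """Raised when the bivariate model cannot be fitted."""


@dataclass
class BivariateFit:
    """Converged bivariate random-effects fit.

    ``fixed_effect_cov`` is the 2×2 covariance of the estimated pooled
    logits (sens first); ``loglik`` is the restricted (or full, for
    ``method='ml'``) log-likelihood at the optimum.
    """

    mu_sens_logit: float
    mu_spec_logit: float
    tau2_sens: float
    tau2_spec: float
    rho: float
    fixed_effect_cov: np.ndarray
    loglik: float
    n_studies: int
    converged: bool
    method: str = "reml"
    diagnostics: dict = field(default_factory=dict)

    @property
    def mu(self) -> np.ndarray:
        return np.array([self.mu_sens_logit, self.mu_spec_logit])

    @property
    def between_cov(self) -> np.ndarray:
        c = self.rho * math.sqrt(self.tau2_sens * self.tau2_spec)
        return np.array([[self.tau2_sens, c], [c, self.tau2_spec]])

    def to_dict(self) -> dict:
        return {
            "mu_sens_logit": self.mu_sens_logit,
            "mu_spec_logit": self.mu_spec_logit,
            "tau2_sens": self.tau2_sens,
            "tau2_spec": self.tau2_spec,
            "rho": self.rho,
            "fixed_effect_cov": np.asarray(self.fixed_effect_cov).tolist(),
            "loglik": self.loglik,
            "n_studies": self.n_studies,
            "converged": self.converged,
            "method": self.method,
        }


@dataclass
class PooledAccuracy:
    """Back-transformed pooled summaries — the published-table row shape."""

    pooled_sens: float
    sens_ci: tuple[float, float]
    pooled_spec: float
    spec_ci: tuple[float, float]
    pplr: float
    pplr_ci: tuple[float, float]
    pnlr: float
    pnlr_ci: tuple[float, float]
    pdor: float
    pdor_ci: tuple[float, float]
    auc: float
    auc_ci: tuple[float, float]
    bivariate_i2: float
    threshold_effect_pct: float

    def to_dict(self) -> dict:
        return {
            "pooled_sens": self.pooled_sens,
            "sens_lo": self.sens_ci[0],
            "sens_hi": self.sens_ci[1],
            "pooled_spec": self.pooled_spec,
            "spec_lo": self.spec_ci[0],
            "spec_hi": self.spec_ci[1],
            "pplr": self.pplr,
            "pplr_lo": self.pplr_ci[0],
            "pplr_hi": self.pplr_ci[1],
            "pnlr": self.pnlr,
            "pnlr_lo": self.pnlr_ci[0],
            "pnlr_hi": self.pnlr_ci[1],
            "pdor": self.pdor,
            "pdor_lo": self.pdor_ci[0],
            "pdor_hi": self.pdor_ci[1],
            "auc": self.auc,
            "auc_lo": self.auc_ci[0],
            "auc_hi": self.auc_ci[1],
            "bivariate_i2": self.bivariate_i2,
            "threshold_effect_pct": self.threshold_effect_pct,
        }


@dataclass
class ComparisonResult:
    """Bivariate meta-regression comparison of two study groups."""

    relative_sensitivity: float
    rel_sens_ci: tuple[float, float]
    relative_specificity: float
    rel_spec_ci: tuple[float, float]
    p_sens: float
    p_spec: float
    p_global: float
    label: str = ""
    n_group1: int = 0
    n_group0: int = 0

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "relative_sensitivity": self.relative_sensitivity,
            "rel_sens_lo": self.rel_sens_ci[0],
            "rel_sens_hi": self.rel_sens_ci[1],
            "relative_specificity": self.relative_specificity,
            "rel_spec_lo": self.rel_spec_ci[0],
            "rel_spec_hi": self.rel_spec_ci[1],
            "p_sens": self.p_sens,
            "p_spec": self.p_spec,
            "p_global": self.p_global,
            "n_group1": self.n_group1,
            "n_group0": self.n_group0,
        }


# ---------------------------------------------------------------------------
# Likelihood machinery


def _extract(studies: Sequence[StudyAccuracy]) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([[s.logit_sens, s.logit_spec] for s in studies], dtype=float)
    s2 = np.array(
        [[s.se_logit_sens**2, s.se_logit_spec**2] for s in studies], dtype=float
    )
    if not (np.isfinite(y).all() and np.isfinite(s2).all()):
        raise FitError("non-finite logits or standard errors")
    return y, s2


def _vinv_terms(theta: np.ndarray, s2: np.ndarray):
    """Elementwise 2×2 inverses of V_i = T + C_i for every study.

    Returns (i11, i12, i22, logdet) arrays.  ``theta`` is the unconstrained
    parameter (log tau1², log tau2², atanh rho).
    """
    lt1, lt2, z = np.clip(theta, [-30.0, -30.0, -6.0], [5.0, 5.0, 6.0])
    t1, t2 = math.exp(lt1), math.exp(lt2)
    rho = math.tanh(z)
    c = rho * math.sqrt(t1 * t2)
    a = t1 + s2[:, 0]
    b = t2 + s2[:, 1]
    det = a * b - c * c
    return b / det, -c / det, a / det, np.log(det)


def _gls(i11, i12, i22, y):
    """GLS mean and its covariance for an intercept-only bivariate model."""
    S = np.array([[i11.sum(), i12.sum()], [i12.sum(), i22.sum()]])
    m = np.array(
        [
            (i11 * y[:, 0] + i12 * y[:, 1]).sum(),
            (i12 * y[:, 0] + i22 * y[:, 1]).sum(),
        ]
    )
    Sinv = np.linalg.inv(S)
    return Sinv @ m, Sinv, S


def _neg_ll(theta: np.ndarray, groups, reml: bool) -> float:
    """−2·(profile log-likelihood)/2 over groups with separate means, shared T."""
    total = 0.0
    for y, s2 in groups:
        i11, i12, i22, logdet = _vinv_terms(theta, s2)
        mu, _, S = _gls(i11, i12, i22, y)
        r1 = y[:, 0] - mu[0]
        r2 = y[:, 1] - mu[1]
        quad_form = (i11 * r1 * r1 + 2.0 * i12 * r1 * r2 + i22 * r2 * r2).sum()
        total += logdet.sum() + quad_form
        if reml:
            sign, logdet_s = np.linalg.slogdet(S)
            if sign <= 0:
                return 1e10
            total += logdet_s
    if not math.isfinite(total):
        return 1e10
    return 0.5 * total


_STARTS = [
    (0.1, 0.1, 0.0),
    (0.3, 0.3, -0.3),
    (0.02, 0.02, 0.0),
    (1.0, 1.0, -0.6),
    (0.5, 0.1, 0.3),
]


def _optimize_cov(groups, reml: bool) -> tuple[np.ndarray, float, bool, dict]:
    """Minimize the (restricted) negative log-likelihood over covariance params.

    Derivative-free Nelder–Mead from five deterministic starting points;
    variances are parametrized on the log scale and the correlation by
    Fisher z, keeping the search unconstrained.
    """
    best = None
    diagnostics = {"starts": []}
    for t1, t2, r in _STARTS:
        x0 = np.array([math.log(t1), math.log(t2), math.atanh(r)])
        res = minimize(
            _neg_ll,
            x0,
            args=(groups, reml),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 800, "maxfev": 1200},
        )
        diagnostics["starts"].append(
            {"x0": x0.tolist(), "fun": float(res.fun), "success": bool(res.success)}
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not math.isfinite(best.fun) or best.fun >= 1e9:
        raise FitError(f"bivariate fit did not converge: {diagnostics}")
    converged = any(s["success"] and abs(s["fun"] - best.fun) < 1e-6 for s in diagnostics["starts"])
    return np.asarray(best.x), float(best.fun), converged, diagnostics


def _theta_to_params(theta: np.ndarray) -> tuple[float, float, float]:
    lt1, lt2, z = np.clip(theta, [-30.0, -30.0, -6.0], [5.0, 5.0, 6.0])
    t1, t2 = math.exp(lt1), math.exp(lt2)
    rho = math.tanh(z)
    # variance floor: treat numerically vanished components as exactly zero
    if t1 < _TAU2_FLOOR:
        t1 = 0.0
    if t2 < _TAU2_FLOOR:
        t2 = 0.0
    if t1 == 0.0 or t2 == 0.0:
        rho = 0.0
    return t1, t2, rho


def fit_bivariate(
    studies: Sequence[StudyAccuracy],
    *,
    method: str = "reml",
    min_studies: int = MIN_STUDIES,
) -> BivariateFit:
    """REML fit of the bivariate normal–normal model to ≥ 4 studies.

    Parameters
    ----------
    studies
        Per-study accuracy statistics (continuity-corrected upstream).
    method
        ``'reml'`` (default) or ``'ml'``; ML is used internally for
        likelihood-ratio comparisons of fixed-effect structures.
    min_studies
        Minimum admissible number of studies, mirroring the usual DTA
        inclusion rule of at least four studies per test.
    """
    if len(studies) < min_studies:
        raise FitError(
            f"bivariate fit requires at least {min_studies} studies, got {len(studies)}"
        )
    if method not in ("reml", "ml"):
        raise ValueError("method must be 'reml' or 'ml'")
    y, s2 = _extract(studies)
    groups = [(y, s2)]
    theta, nll, converged, diagnostics = _optimize_cov(groups, reml=(method == "reml"))
    t1, t2, rho = _theta_to_params(theta)
    i11, i12, i22, _ = _vinv_terms(theta, s2)
    mu, fixed_cov, _ = _gls(i11, i12, i22, y)
    k = len(studies)
    const = -k * math.log(2.0 * math.pi)
    return BivariateFit(
        mu_sens_logit=float(mu[0]),
        mu_spec_logit=float(mu[1]),
        tau2_sens=t1,
        tau2_spec=t2,
        rho=rho,
        fixed_effect_cov=fixed_cov,
        loglik=const - nll,
        n_studies=k,
        converged=converged,
        method=method,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# Pooled summaries


def _mc_draws(fit: BivariateFit, n_draws: int, seed: int) -> np.ndarray:
    cov = np.asarray(fit.fixed_effect_cov, dtype=float)
    cov = 0.5 * (cov + cov.T)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() < -1e-10:
        raise FitError("fixed-effect covariance is not positive semi-definite")
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(fit.mu, cov, size=n_draws, method="svd")


def pooled_summaries(
    fit: BivariateFit,
    studies: Sequence[StudyAccuracy] | None = None,
    *,
    n_draws: int = 100_000,
    seed: int = MC_SEED,
    auc_grid: int = 2001,
) -> PooledAccuracy:
    """Back-transform the fit into pooled Se/Sp/PLR/NLR/DOR/AUC with 95% CIs.

    Sensitivity/specificity intervals are Wald on the logit scale; intervals
    for the derived ratios (PLR, NLR, DOR) and the SROC AUC propagate the
    fixed-effect covariance by parametric Monte Carlo (percentile intervals
    on ``n_draws`` multivariate-normal draws, fixed seed for reproducible
    reports).  ``studies`` is only needed for the bivariate I² component.
    """
    se_mu = np.sqrt(np.diag(np.asarray(fit.fixed_effect_cov)))
    sens = float(expit(fit.mu_sens_logit))
    spec = float(expit(fit.mu_spec_logit))
    sens_ci = (
        float(expit(fit.mu_sens_logit - Z95 * se_mu[0])),
        float(expit(fit.mu_sens_logit + Z95 * se_mu[0])),
    )
    spec_ci = (
        float(expit(fit.mu_spec_logit - Z95 * se_mu[1])),
        float(expit(fit.mu_spec_logit + Z95 * se_mu[1])),
    )
    plr = sens / (1.0 - spec)
    nlr = (1.0 - sens) / spec
    dor = plr / nlr

    draws = _mc_draws(fit, n_draws, seed)
    se_d = expit(draws[:, 0])
    sp_d = expit(draws[:, 1])
    plr_d = se_d / (1.0 - sp_d)
    nlr_d = (1.0 - se_d) / sp_d
    dor_d = plr_d / nlr_d

    def _pct(x: np.ndarray) -> tuple[float, float]:
        lo, hi = np.percentile(x, [2.5, 97.5])
        return float(lo), float(hi)

    # AUC point and MC interval (fixed effects propagated, T held at estimate)
    _, _, auc = sroc_curve_and_auc(fit, grid_size=auc_grid)
    auc_draw_n = min(n_draws, 2000)
    auc_draws = _sroc_auc_vectorized(fit, draws[:auc_draw_n], grid_size=512)
    auc_ci = _pct(auc_draws)

    i2 = bivariate_i2(fit, studies) if studies is not None else float("nan")
    return PooledAccuracy(
        pooled_sens=sens,
        sens_ci=sens_ci,
        pooled_spec=spec,
        spec_ci=spec_ci,
        pplr=plr,
        pplr_ci=_pct(plr_d),
        pnlr=nlr,
        pnlr_ci=_pct(nlr_d),
        pdor=dor,
        pdor_ci=_pct(dor_d),
        auc=auc,
        auc_ci=auc_ci,
        bivariate_i2=i2,
        threshold_effect_pct=threshold_effect_proportion(fit),
    )


# ---------------------------------------------------------------------------
# SROC curve and AUC


def _sroc_slope(fit: BivariateFit) -> float:
    """Slope of the model-implied regression of logit-sens on logit-spec."""
    if fit.tau2_spec <= 0.0:
        return 0.0
    return fit.rho * math.sqrt(fit.tau2_sens * fit.tau2_spec) / fit.tau2_spec


def sroc_sens_at_fpr(fit: BivariateFit, fpr: np.ndarray) -> np.ndarray:
    """Summary-ROC sensitivity at the given false-positive rates.

    Traced as the regression of logit-sensitivity on logit-specificity
    implied by the between-study covariance:
    ``logit se = mu1 + b * (logit(1-fpr) - mu2)`` with
    ``b = rho*tau1*tau2 / tau2^2``; when ``tau2^2 = 0`` the curve is the
    constant-sensitivity line.  Endpoint values at fpr 0 and 1 are the
    analytic limits of the same expression.
    """
    fpr = np.asarray(fpr, dtype=float)
    b = _sroc_slope(fit)
    if b == 0.0:
        return np.full(fpr.shape, float(expit(fit.mu_sens_logit)))
    out = np.empty(fpr.shape, dtype=float)
    interior = (fpr > 0.0) & (fpr < 1.0)
    lspec = logit(1.0 - fpr[interior])
    out[interior] = expit(fit.mu_sens_logit + b * (lspec - fit.mu_spec_logit))
    # limits: logit(1-fpr) -> +inf as fpr->0, -inf as fpr->1
    out[fpr == 0.0] = 1.0 if b > 0 else 0.0
    out[fpr == 1.0] = 0.0 if b > 0 else 1.0
    return out


def sroc_curve_and_auc(
    fit: BivariateFit, grid_size: int = 1001
) -> tuple[np.ndarray, np.ndarray, float]:
    """SROC curve points on a uniform fpr grid plus the trapezoidal AUC.

    The AUC integrates sensitivity over the full fpr range [0, 1]; use
    :func:`sroc_partial_auc` to restrict to an observed fpr window.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be at least 2")
    fpr = np.linspace(0.0, 1.0, grid_size)
    sens = sroc_sens_at_fpr(fit, fpr)
    auc = float(np.trapezoid(sens, fpr))
    return fpr, sens, auc


def sroc_partial_auc(fit: BivariateFit, fpr_lo: float, fpr_hi: float, grid_size: int = 1001) -> float:
    """Trapezoidal AUC restricted to ``[fpr_lo, fpr_hi]`` (option flag use)."""
    if grid_size < 2:
        raise ValueError("grid_size must be at least 2")
    fpr = np.linspace(fpr_lo, fpr_hi, grid_size)
    return float(np.trapezoid(sroc_sens_at_fpr(fit, fpr), fpr))


def _sroc_auc_vectorized(fit: BivariateFit, mus: np.ndarray, grid_size: int) -> np.ndarray:
    """AUC for many fixed-effect draws at the fitted between-study covariance."""
    b = _sroc_slope(fit)
    fpr = np.linspace(0.0, 1.0, grid_size)
    if b == 0.0:
        return expit(mus[:, 0])  # constant curve integrates to its level
    lspec = logit(1.0 - fpr[1:-1])
    se = expit(mus[:, [0]] + b * (lspec[None, :] - mus[:, [1]]))
    ends_lo = np.full((mus.shape[0], 1), 1.0 if b > 0 else 0.0)
    ends_hi = np.full((mus.shape[0], 1), 0.0 if b > 0 else 1.0)
    curve = np.hstack([ends_lo, se, ends_hi])
    return np.trapezoid(curve, fpr, axis=1)


def sroc_auc_quad(fit: BivariateFit) -> float:
    """Adaptive-quadrature AUC of the same SROC curve (cross-check oracle)."""
    val, _ = quad(lambda f: float(sroc_sens_at_fpr(fit, np.array([f]))[0]), 0.0, 1.0, limit=200)
    return float(val)


# ---------------------------------------------------------------------------
# Heterogeneity diagnostics


def _typical_within_cov(studies: Sequence[StudyAccuracy]) -> np.ndarray:
    """Typical within-study covariance (Higgins' s² per component, 0 off-diagonal)."""
    _, s2 = _extract(studies)
    k = s2.shape[0]
    out = np.zeros((2, 2))
    for j in (0, 1):
        w = 1.0 / s2[:, j]
        sw, sw2 = w.sum(), (w * w).sum()
        out[j, j] = (k - 1) * sw / (sw * sw - sw2)
    return out


def bivariate_i2(fit: BivariateFit, studies: Sequence[StudyAccuracy]) -> float:
    """Generalized (determinant-based) bivariate I², in percent.

    Between-study variability over total variability, with matrices reduced
    to scalars through the square root of their determinants (the
    generalized-variance construction): ``I² = |T|^½ / (|T|^½ + |W|^½)``,
    where W is the typical within-study covariance.
    """
    T = fit.between_cov
    W = _typical_within_cov(studies)
    gt = math.sqrt(max(float(np.linalg.det(T)), 0.0))
    gw = math.sqrt(max(float(np.linalg.det(W)), 0.0))
    if gt + gw == 0.0:
        return 0.0
    return 100.0 * gt / (gt + gw)


def higgins_i2(values: np.ndarray, variances: np.ndarray) -> float:
    """Univariate Higgins I² (DerSimonian–Laird Q construction), in percent."""
    w = 1.0 / np.asarray(variances, dtype=float)
    y = np.asarray(values, dtype=float)
    k = y.size
    if k < 2:
        return 0.0
    ybar = (w * y).sum() / w.sum()
    q = float((w * (y - ybar) ** 2).sum())
    if q <= 0.0:
        return 0.0
    return max(0.0, 100.0 * (q - (k - 1)) / q)


def threshold_effect_proportion(fit: BivariateFit) -> float:
    """Percent of between-study heterogeneity attributed to a threshold effect.

    Defined as ``rho² × 100`` when the estimated correlation has threshold
    orientation (negative correlation between logit-sens and logit-spec,
    i.e. positive between sens and the false-positive rate), else 0.  This
    is one defensible operationalization of "proportion of heterogeneity
    due to the threshold effect"; it is reported prominently as such.
    """
    if fit.rho < 0.0:
        return 100.0 * fit.rho**2
    return 0.0


# ---------------------------------------------------------------------------
# Outlier detection


@dataclass
class OutlierReport:
    study_id: str
    z_sens: float
    z_spec: float
    flagged: bool


def detect_outliers(
    fit: BivariateFit, studies: Sequence[StudyAccuracy], *, cutoff: float = 2.0
) -> list[OutlierReport]:
    """Standardized empirical-Bayes level-2 residuals with |z| > 2 flags.

    The EB predicted random effect for study i is ``b_i = T V_i⁻¹ (y_i − μ̂)``
    and is standardized component-wise by the square root of
    ``diag(T V_i⁻¹ T)`` — the sampling variance of the predictor under the
    model — so each z is approximately standard normal when the study is
    exchangeable with the rest.  A study is flagged when either component
    strictly exceeds the cutoff in absolute value.  When the between-study
    covariance is estimated as zero there are no study-level effects to
    predict and nothing is flagged.
    """
    y, s2 = _extract(studies)
    T = fit.between_cov
    if float(np.linalg.det(T)) <= 0.0 and float(np.trace(T)) <= 0.0:
        return [OutlierReport(s.study_id, 0.0, 0.0, False) for s in studies]
    mu = fit.mu
    out = []
    for i, s in enumerate(studies):
        V = T + np.diag(s2[i])
        Vinv = np.linalg.inv(V)
        b = T @ Vinv @ (y[i] - mu)
        var_b = np.diag(T @ Vinv @ T)
        z = np.where(var_b > 0, b / np.sqrt(np.maximum(var_b, 1e-300)), 0.0)
        flagged = bool(np.any(np.abs(z) > cutoff))
        out.append(OutlierReport(s.study_id, float(z[0]), float(z[1]), flagged))
    return out


def refit_without_outliers(
    fit: BivariateFit, studies: Sequence[StudyAccuracy], *, cutoff: float = 2.0
) -> tuple[BivariateFit, list[StudyAccuracy], list[OutlierReport]]:
    """Sensitivity analysis: flag outliers, drop them, and refit."""
    reports = detect_outliers(fit, studies, cutoff=cutoff)
    flagged_ids = {r.study_id for r in reports if r.flagged}
    kept = [s for s in studies if s.study_id not in flagged_ids]
    if not flagged_ids or len(kept) < MIN_STUDIES:
        return fit, list(studies), reports
    return fit_bivariate(kept, method=fit.method), kept, reports


# ---------------------------------------------------------------------------
# Group comparison / meta-regression


def _group_mu_cov(theta: np.ndarray, y: np.ndarray, s2: np.ndarray):
    i11, i12, i22, _ = _vinv_terms(theta, s2)
    mu, cov, _ = _gls(i11, i12, i22, y)
    return mu, cov


def compare_groups(
    studies: Sequence[StudyAccuracy],
    group_indicator: Sequence[bool],
    *,
    min_per_group: int = MIN_STUDIES,
    label: str = "",
    n_draws: int = 100_000,
    seed: int = MC_SEED,
) -> ComparisonResult:
    """Compare diagnostic accuracy between two study groups.

    A joint bivariate model with the binary indicator entering both logit
    equations (equivalently: group-specific means with a shared between-study
    covariance) is fitted by maximum likelihood; the null model pools the
    means.  The global 2-df likelihood-ratio test asks whether the indicator
    shifts the (sens, spec) pair at all; per-component Wald tests and
    Monte-Carlo intervals for the relative sensitivity/specificity
    (group 1 over group 0, on the probability scale) localize the effect.
    """
    ind = np.asarray(group_indicator, dtype=bool)
    if len(ind) != len(studies):
        raise ValueError("group_indicator length must match studies")
    g1 = [s for s, g in zip(studies, ind) if g]
    g0 = [s for s, g in zip(studies, ind) if not g]
    if len(g1) < min_per_group or len(g0) < min_per_group:
        raise FitError(
            f"each group needs at least {min_per_group} studies "
            f"(got {len(g1)} vs {len(g0)})"
        )
    y1, s21 = _extract(g1)
    y0, s20 = _extract(g0)

    # alternative: separate means, shared covariance (ML for the LRT)
    theta_alt, nll_alt, conv_alt, _ = _optimize_cov([(y1, s21), (y0, s20)], reml=False)
    # null: common mean
    yall = np.vstack([y1, y0])
    s2all = np.vstack([s21, s20])
    _, nll_null, conv_null, _ = _optimize_cov([(yall, s2all)], reml=False)
    if not (conv_alt and conv_null):
        raise FitError("group-comparison fits did not converge")
    lrt = max(0.0, 2.0 * (nll_null - nll_alt))
    p_global = float(chi2.sf(lrt, df=2))

    mu1, cov1 = _group_mu_cov(theta_alt, y1, s21)
    mu0, cov0 = _group_mu_cov(theta_alt, y0, s20)

    # per-component Wald tests of the indicator coefficient
    diff = mu1 - mu0
    se_diff = np.sqrt(np.diag(cov1) + np.diag(cov0))
    z = diff / se_diff
    p_sens, p_spec = (float(2.0 * norm.sf(abs(v))) for v in z)

    rng = np.random.default_rng(seed)
    d1 = rng.multivariate_normal(mu1, 0.5 * (cov1 + cov1.T), size=n_draws, method="svd")
    d0 = rng.multivariate_normal(mu0, 0.5 * (cov0 + cov0.T), size=n_draws, method="svd")
    ratios = expit(d1) / expit(d0)

    def _pct(x):
        lo, hi = np.percentile(x, [2.5, 97.5])
        return float(lo), float(hi)

    return ComparisonResult(
        relative_sensitivity=float(expit(mu1[0]) / expit(mu0[0])),
        rel_sens_ci=_pct(ratios[:, 0]),
        relative_specificity=float(expit(mu1[1]) / expit(mu0[1])),
        rel_spec_ci=_pct(ratios[:, 1]),
        p_sens=p_sens,
        p_spec=p_spec,
        p_global=p_global,
        label=label,
        n_group1=len(g1),
        n_group0=len(g0),
    )


#: covariate name → (predicate on Study2x2Record, group-1 label, group-0 label)
LATE_STAGE_BOUNDARY = 0.5


def subgroup_indicator(records, covariate: str) -> tuple[list, list[bool], str]:
    """Build the binary split for a named covariate.

    Supported covariates: ``pct_late_stage`` (late-majority: > 50% late
    stage; exactly 50% counts as early-majority), ``assay_method`` (non-CLIA
    vs CLIA), ``control_composition`` (healthy vs benign; mixed/unknown
    dropped).  Returns (records used, indicator, label).
    """
    if covariate == "pct_late_stage":
        used = [r for r in records if r.pct_late_stage is not None]
        ind = [r.pct_late_stage > LATE_STAGE_BOUNDARY for r in used]
        lab = "late_vs_early_stage"
    elif covariate == "assay_method":
        used = [r for r in records if r.assay_method != "unknown"]
        ind = [r.assay_method != "CLIA" for r in used]
        lab = "non_clia_vs_clia"
    elif covariate == "control_composition":
        used = [r for r in records if r.control_composition in ("healthy", "benign")]
        ind = [r.control_composition == "healthy" for r in used]
        lab = "healthy_vs_benign_controls"
    else:
        raise ValueError(f"unsupported subgroup covariate: {covariate!r}")
    return used, ind, lab


def subgroup_analysis(
    records,
    accuracies: Sequence[StudyAccuracy],
    covariate: str,
    *,
    min_per_level: int = 2,
    seed: int = MC_SEED,
) -> ComparisonResult:
    """Within-biomarker subgroup comparison on a named binary covariate.

    Identical machinery to :func:`compare_groups`; the per-level minimum is
    relaxed to 2 because the between-study covariance is shared across all
    studies in the joint model.
    """
    by_id = {a.study_id: a for a in accuracies}
    used_all, ind_all, lab = subgroup_indicator(records, covariate)
    pairs = [(r, i) for r, i in zip(used_all, ind_all) if r.study_id in by_id]
    used = [r for r, _ in pairs]
    ind = [i for _, i in pairs]
    n1, n0 = sum(ind), len(ind) - sum(ind)
    if n1 < min_per_level or n0 < min_per_level:
        raise FitError(
            f"subgroup {covariate!r} needs ≥{min_per_level} studies per level (got {n1} vs {n0})"
        )
    accs = [by_id[r.study_id] for r in used]
    return compare_groups(
        accs, ind, min_per_group=min_per_level, label=lab, seed=seed
    )
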