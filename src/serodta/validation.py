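"""Patient-level validation statistics for matched case-control biomarker cohorts.

Covers the direct-comparison arm of the pipeline: nonparametric ROC/AUC with
the Hanley–McNeil standard error, the z-test for independent AUCs,
logistic-regression combination of biomarker panels, paired case/control
location tests, and kit-cutoff dichotomization that turns a cohort into the
2×2 study record consumed by the meta-analytic stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata, ttest_rel, wilcoxon

from .dta_core import Study2x2Record, Z95

GROUPS = ("case", "control")
STAGES = ("early", "late", "none")
HISTOLOGIES = ("LUAD", "LUSC", "LLCC", "none")
CONTROL_TYPES = ("healthy", "benign", "none")

#: manufacturer kit positivity cutoffs (value >= cutoff is positive)
KIT_CUTOFFS: dict[str, float] = {
    "CEA": 5.00,  # ng/mL
    "CYFRA211": 3.3,  # ug/L
    "HE4": 70.0,  # pmol/L
    "SAA": 10.0,  # mg/L
}

BIOMARKER_UNITS: dict[str, str] = {
    "CEA": "ng/mL",
    "CYFRA211": "ug/L",
    "HE4": "pmol/L",
    "SAA": "mg/L",
}

AGE_DICHOTOMY = 65  # "over 65" vs younger

COHORT_CSV_COLUMNS = [
    "subject_id",
    "group",
    "pair_id",
    "age",
    "sex",
    "stage",
    "histology",
    "control_type",
    "CEA",
    "CYFRA211",
    "HE4",
    "SAA",
]


@dataclass(frozen=True)
class PatientRecord:
    """A matched case-control subject with continuous biomarker values."""

    subject_id: str
    group: str  # case | control
    pair_id: str
    biomarker_values: Mapping[str, float]
    age: float
    sex: str
    stage: str = "none"
    histology: str = "none"
    control_type: str = "none"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"{self.subject_id}: group must be case or control")
        if self.stage not in STAGES:
            raise ValueError(f"{self.subject_id}: invalid stage {self.stage!r}")
        if self.histology not in HISTOLOGIES:
            raise ValueError(f"{self.subject_id}: invalid histology {self.histology!r}")
        if self.control_type not in CONTROL_TYPES:
            raise ValueError(f"{self.subject_id}: invalid control_type")
        if self.group == "control" and (self.stage != "none" or self.histology != "none"):
            raise ValueError(f"{self.subject_id}: controls carry no stage/histology")
        for b, v in self.biomarker_values.items():
            if v is not None and v < 0:
                raise ValueError(f"{self.subject_id}: negative value for {b}")


def validate_cohort(records: Sequence[PatientRecord]) -> None:
    """Check the 1:1 matching invariant: each pair_id once per group."""
    seen: dict[tuple[str, str], int] = {}
    for r in records:
        key = (r.pair_id, r.group)
        seen[key] = seen.get(key, 0) + 1
        if seen[key] > 1:
            raise ValueError(f"pair_id {r.pair_id!r} appears twice in group {r.group}")


@dataclass
class AUCEstimate:
    """Nonparametric AUC with the Hanley–McNeil closed-form standard error."""

    auc: float
    se: float
    n_cases: int
    n_controls: int
    ci: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "se": self.se,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "auc_lo": self.ci[0],
            "auc_hi": self.ci[1],
        }


def hanley_mcneil_se(auc: float, n_cases: int, n_controls: int) -> float:
    """Closed-form SE of a nonparametric AUC (Q1 = A/(2−A), Q2 = 2A²/(1+A))."""
    a = auc
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a)
        + (n_cases - 1) * (q1 - a * a)
        + (n_controls - 1) * (q2 - a * a)
    ) / (n_cases * n_controls)
    return math.sqrt(max(var, 0.0))


def empirical_auc(values: Sequence[float], labels: Sequence[str]) -> AUCEstimate:
    """Mann–Whitney AUC (ties count 0.5) with a Hanley–McNeil Wald interval.

    ``labels`` holds ``'case'``/``'control'`` per value.  The AUC equals the
    probability that a random case exceeds a random control, estimated by
    the normalized rank sum; the interval is truncated to [0, 1].
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    case = v[lab == "case"]
    ctrl = v[lab == "control"]
    n1, n0 = case.size, ctrl.size
    if n1 == 0 or n0 == 0:
        raise ValueError("need at least one case and one control")
    ranks = rankdata(np.concatenate([case, ctrl]))
    auc = (ranks[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    se = hanley_mcneil_se(auc, n1, n0)
    ci = (max(0.0, auc - Z95 * se), min(1.0, auc + Z95 * se))
    return AUCEstimate(auc=float(auc), se=se, n_cases=n1, n_controls=n0, ci=ci)


def compare_auc_independent(a: AUCEstimate, b: AUCEstimate) -> tuple[float, float]:
    """Hanley–McNeil z-test for two AUCs from independent samples.

    z = (A1 − A2)/sqrt(SE1² + SE2²), two-sided normal p-value.  Applying it
    to curves measured on the same subjects ignores their correlation — a
    deliberate reproduction of common practice that makes the test
    conservative for positively correlated markers.
    """
    denom = math.sqrt(a.se**2 + b.se**2)
    if denom == 0.0:
        raise ValueError("combined standard error is zero")
    z = (a.auc - b.auc) / denom
    return float(z), float(2.0 * norm.sf(abs(z)))


@dataclass
class CombinationResult:
    scores: np.ndarray
    auc: AUCEstimate
    coefficients: dict[str, float]
    ridge_fallback: bool = False
    biomarkers: list[str] = field(default_factory=list)


def combine_biomarkers(
    value_matrix: pd.DataFrame,
    labels: Sequence[str],
    biomarker_subset: Sequence[str],
    *,
    log_scale: bool = True,
    ridge_penalty: float = 1e-4,
) -> CombinationResult:
    """Logistic-regression combination of a biomarker panel.

    Fits case/control status on the (by default log-transformed) biomarker
    values by maximum likelihood and scores each subject by the fitted
    linear predictor; the panel's AUC is the AUC of those scores.  Under
    perfect separation the ML fit diverges, so a ridge-penalized refit
    (penalty 1e-4) is used and flagged.
    """
    import statsmodels.api as sm

    subset = list(biomarker_subset)
    X = value_matrix[subset].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing biomarker values in the requested subset")
    if log_scale:
        if (X <= 0).any():
            raise ValueError("log transform requires strictly positive values")
        X = np.log(X)
    y = (np.asarray(labels) == "case").astype(float)
    if y.min() == y.max():
        raise ValueError("both classes must be present")

    ridge = False
    Xc = sm.add_constant(X)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", False))
        coefs = np.asarray(fit.params)
        if not converged or not np.isfinite(coefs).all() or np.abs(coefs).max() > 1e3:
            raise RuntimeError("non-converged ML fit")
    except Exception:
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=1.0 / ridge_penalty, max_iter=5000)
        lr.fit(X, y)
        coefs = np.concatenate([lr.intercept_, lr.coef_.ravel()])
        ridge = True

    scores = Xc @ coefs if not ridge else coefs[0] + X @ coefs[1:]
    auc = empirical_auc(scores, np.where(y == 1.0, "case", "control"))
    return CombinationResult(
        scores=np.asarray(scores),
        auc=auc,
        coefficients={"const": float(coefs[0]), **{b: float(c) for b, c in zip(subset, coefs[1:])}},
        ridge_fallback=ridge,
        biomarkers=subset,
    )


def paired_group_test(
    case_values: Sequence[float], matched_control_values: Sequence[float]
) -> tuple[float, float, dict]:
    """Paired location test on matched case/control vectors.

    Returns the Wilcoxon signed-rank statistic and p-value (the default
    inference) plus a record of both methods: the paired t-test p-value is
    reported alongside.  All-zero differences yield p = 1 with a note.
    """
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(matched_control_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("matched vectors must have equal length")
    d = x - y
    t_stat, t_p = ttest_rel(x, y)
    if np.all(d == 0.0):
        return 0.0, 1.0, {
            "method_used": "wilcoxon",
            "note": "all paired differences are zero",
            "t_p": 1.0,
            "wilcoxon_p": 1.0,
        }
    w_stat, w_p = wilcoxon(x, y)
    return float(w_stat), float(w_p), {
        "method_used": "wilcoxon",
        "wilcoxon_p": float(w_p),
        "t_stat": float(t_stat),
        "t_p": float(t_p),
    }


# ---------------------------------------------------------------------------
# Kit-cutoff dichotomization


def dichotomize_by_cutoff(record: PatientRecord, biomarker: str, cutoff: float) -> bool:
    """True (positive) iff the biomarker value is at or above the cutoff.

    Kit inserts state the negative side ("< cutoff is negative"), so a value
    exactly at the cutoff is positive.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    value = record.biomarker_values.get(biomarker)
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise KeyError(f"{record.subject_id}: no value for {biomarker}")
    return value >= cutoff


def cohort_to_2x2(
    records: Sequence[PatientRecord],
    biomarker: str,
    cutoff: float | None = None,
    *,
    study_id: str | None = None,
) -> tuple[Study2x2Record, list[str]]:
    """Aggregate a cohort into the experimental 2×2 study record.

    Subjects missing the biomarker are excluded and listed in the returned
    log.  Covariates are derived from the cohort: control composition from
    the control mix, late-stage percentage from the cases, CLIA as the
    assay method of the experimental measurements.
    """
    if cutoff is None:
        cutoff = KIT_CUTOFFS[biomarker]
    tp = fp = fn = tn = 0
    excluded: list[str] = []
    control_types = set()
    n_late = n_cases = 0
    for r in records:
        try:
            positive = dichotomize_by_cutoff(r, biomarker, cutoff)
        except KeyError:
            excluded.append(f"{r.subject_id}: missing {biomarker}")
            continue
        if r.group == "case":
            n_cases += 1
            n_late += int(r.stage == "late")
            tp += int(positive)
            fn += int(not positive)
        else:
            control_types.add(r.control_type)
            fp += int(positive)
            tn += int(not positive)
    if control_types <= {"healthy"}:
        comp = "healthy"
    elif control_types <= {"benign"}:
        comp = "benign"
    else:
        comp = "mixed"
    rec = Study2x2Record(
        study_id=study_id or f"experimental_{biomarker}",
        biomarker=biomarker,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        control_composition=comp,
        pct_late_stage=(n_late / n_cases) if n_cases else None,
        assay_method="CLIA",
        design="case_control",
        extra_covariates={"source": "experiment"},
    )
    return rec, excluded


# ---------------------------------------------------------------------------
# Covariate stratification (per-stratum AUCs + independent-curve comparisons)


def stratified_auc(
    records: Sequence[PatientRecord], biomarker: str, stratum: str
) -> dict[str, AUCEstimate]:
    """Per-stratum AUCs for one biomarker.

    ``stratum`` ∈ {'stage', 'histology', 'age', 'control_type'}.  Case-side
    strata (stage, histology) compare the case subset against all controls;
    'age' splits both sides at 65 years; 'control_type' compares all cases
    against each control subset.
    """
    cases = [r for r in records if r.group == "case"]
    controls = [r for r in records if r.group == "control"]

    def _auc(case_sub, ctrl_sub):
        vals = [r.biomarker_values[biomarker] for r in case_sub + ctrl_sub]
        labs = ["case"] * len(case_sub) + ["control"] * len(ctrl_sub)
        return empirical_auc(vals, labs)

    out: dict[str, AUCEstimate] = {}
    if stratum == "stage":
        for level in ("early", "late"):
            sub = [r for r in cases if r.stage == level]
            if sub:
                out[level] = _auc(sub, controls)
    elif stratum == "histology":
        for level in ("LUAD", "LUSC", "LLCC"):
            sub = [r for r in cases if r.histology == level]
            if sub:
                out[level] = _auc(sub, controls)
    elif stratum == "age":
        young_c = [r for r in cases if r.age <= AGE_DICHOTOMY]
        old_c = [r for r in cases if r.age > AGE_DICHOTOMY]
        young_k = [r for r in controls if r.age <= AGE_DICHOTOMY]
        old_k = [r for r in controls if r.age > AGE_DICHOTOMY]
        if young_c and young_k:
            out["age_le_65"] = _auc(young_c, young_k)
        if old_c and old_k:
            out["age_gt_65"] = _auc(old_c, old_k)
    elif stratum == "control_type":
        for level in ("healthy", "benign"):
            sub = [r for r in controls if r.control_type == level]
            if sub:
                out[level] = _auc(cases, sub)
    else:
        raise ValueError(f"unknown stratum {stratum!r}")
    return out


# ---------------------------------------------------------------------------
# CSV interface


def read_cohort_csv(path) -> list[PatientRecord]:
    df = pd.read_csv(path, dtype={"subject_id": str, "pair_id": str}, float_precision="round_trip")
    records = []
    for row in df.to_dict(orient="records"):
        values = {}
        for b in KIT_CUTOFFS:
            v = row.get(b)
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                values[b] = float(v)
        records.append(
            PatientRecord(
                subject_id=row["subject_id"],
                group=row["group"],
                pair_id=row["pair_id"],
                biomarker_values=values,
                age=float(row["age"]),
                sex=str(row["sex"]),
                stage=str(row.get("stage", "none") or "none"),
                histology=str(row.get("histology", "none") or "none"),
                control_type=str(row.get("control_type", "none") or "none"),
            )
        )
    validate_cohort(records)
    return records


def write_cohort_csv(records: Sequence[PatientRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "pair_id": r.pair_id,
                "age": r.age,
                "sex": r.sex,
                "stage": r.stage,
                "histology": r.histology,
                "control_type": r.control_type,
                # repr keeps the shortest round-tripping decimal form
                **{
                    b: (repr(float(r.biomarker_values[b])) if b in r.biomarker_values else "")
                    for b in KIT_CUTOFFS
                },
            }
        )
    pd.DataFrame(rows, columns=COHORT_CSV_COLUMNS).to_csv(path, index=False)


def cohort_frame(records: Sequence[PatientRecord], biomarkers: Sequence[str]) -> tuple[pd.DataFrame, list[str]]:
    """Value matrix + labels for the subjects with complete data on ``biomarkers``."""
    rows, labels = [], []
    for r in records:
        if all(b in r.biomarker_values for b in biomarkers):
            rows.append({b: r.biomarker_values[b] for b in biomarkers})
            labels.append(r.group)
    return pd.DataFrame(rows), labels
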