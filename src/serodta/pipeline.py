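"""Three-step evidence pipeline and interpreted reporting.

Step 1 filters biomarkers for clinical applicability, fits the bivariate
model per biomarker, grades the evidence with the LMBP rules, compares
biomarkers pairwise, and runs outlier and publication-bias diagnostics.
Step 2 computes the matched case-control validation statistics and converts
the cohort into experimental 2×2 rows via the kit cutoffs.  Step 3 appends
those rows to the outlier-excluded study sets, refits, and examines
covariates (tumor stage, assay method, control composition) as sources of
heterogeneity, emitting pooled-accuracy and subgroup tables with
interpretation bands.

Every number in a rendered report is a field of the machine-readable JSON
bundle; re-running any step with the same inputs and seed is byte-identical.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import bivariate as bv
from . import lmbp
from . import publication_bias as pb
from . import validation as vr
from .dta_core import (
    Study2x2Record,
    apply_continuity_correction,
    round_half_up,
    study_accuracy,
)

#: interpretation-band definitions (partition of each domain, edge to the
#: stronger-evidence side; AUC banded after rounding to 2 decimals)
AUC_BANDS = {"not_acceptable": (0.0, 0.70), "acceptable": (0.71, 0.79), "good": (0.80, 0.89), "excellent": (0.90, 1.0)}
PPLR_BANDS = {"substantial": 10.0, "moderate": 5.0, "small": 2.0}
PNLR_BANDS = {"substantial": 0.1, "moderate": 0.2, "small": 0.5}

HIGGINS_SUBGROUP_TRIGGER = 50.0  # percent


def interpret_auc(auc: float) -> str:
    """Band an AUC: ≤0.70 not acceptable, 0.71–0.79 acceptable, 0.80–0.89
    good, 0.90–1 excellent (applied to the value rounded to 2 decimals)."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError("AUC must lie in [0, 1]")
    if auc < 0.5:
        warnings.warn(f"AUC {auc:.3f} is worse than chance", stacklevel=2)
    pct = int(round(round_half_up(auc, 2) * 100))
    if pct <= 70:
        return "not_acceptable"
    if pct <= 79:
        return "acceptable"
    if pct <= 89:
        return "good"
    return "excellent"


def interpret_lr(plr: float, nlr: float) -> tuple[str, str]:
    """Band the likelihood-ratio pair as (rule-in, rule-out) evidence.

    PPLR: >10 substantial, 5–10 moderate, 2–5 small, <2 not meaningful;
    PNLR: <0.1 substantial, 0.1–0.2 moderate, 0.2–0.5 small, >0.5 not
    meaningful.  Band edges go to the stronger-evidence side.
    """
    if plr <= 0 or nlr <= 0:
        raise ValueError("likelihood ratios must be positive")
    if plr >= PPLR_BANDS["substantial"]:
        rule_in = "substantial"
    elif plr >= PPLR_BANDS["moderate"]:
        rule_in = "moderate"
    elif plr >= PPLR_BANDS["small"]:
        rule_in = "small"
    else:
        rule_in = "not_meaningful"
    if nlr <= PNLR_BANDS["substantial"]:
        rule_out = "substantial"
    elif nlr <= PNLR_BANDS["moderate"]:
        rule_out = "moderate"
    elif nlr <= PNLR_BANDS["small"]:
        rule_out = "small"
    else:
        rule_out = "not_meaningful"
    return rule_in, rule_out


# ---------------------------------------------------------------------------
# serialization helpers


def record_to_dict(r: Study2x2Record) -> dict:
    d = asdict(r)
    d["extra_covariates"] = dict(d["extra_covariates"])
    return d


def record_from_dict(d: Mapping) -> Study2x2Record:
    return Study2x2Record(**d)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


class PipelineError(RuntimeError):
    def __init__(self, stage: str, context: str, cause: Exception):
        super().__init__(f"[{stage}] {context}: {cause}")
        self.stage = stage
        self.context = context
        self.cause = cause


def _analyse_biomarker(
    biomarker: str,
    records: Sequence[Study2x2Record],
    *,
    seed: int,
    exclude_outliers: bool = True,
) -> dict:
    """Fit + summarize one biomarker's study set (shared by steps 1 and 3)."""
    corrected = [apply_continuity_correction(r) for r in records]
    accs = [study_accuracy(r) for r in corrected]
    fit = bv.fit_bivariate(accs)
    outlier_reports = bv.detect_outliers(fit, accs)
    if exclude_outliers:
        refit, kept_accs, outlier_reports = bv.refit_without_outliers(fit, accs)
    else:
        refit, kept_accs = fit, accs
    kept_ids = {a.study_id for a in kept_accs}
    kept_records = [r for r in records if r.study_id in kept_ids]
    pooled = bv.pooled_summaries(refit, kept_accs, seed=seed)
    fpr, sens, _ = bv.sroc_curve_and_auc(refit, grid_size=101)
    deeks = pb.deeks_test(kept_records) if len(kept_records) >= 4 else None

    y = np.array([[a.logit_sens, a.logit_spec] for a in kept_accs])
    s2 = np.array([[a.se_logit_sens**2, a.se_logit_spec**2] for a in kept_accs])
    higgins = {
        "sens": bv.higgins_i2(y[:, 0], s2[:, 0]),
        "spec": bv.higgins_i2(y[:, 1], s2[:, 1]),
    }

    return {
        "biomarker": biomarker,
        "n_studies": len(records),
        "n_retained": len(kept_records),
        "fit_full": fit.to_dict(),
        "fit": refit.to_dict(),
        "outliers": [asdict(o) for o in outlier_reports],
        "outliers_excluded": [r.study_id for r in records if r.study_id not in kept_ids],
        "pooled": pooled.to_dict(),
        "interpretation": {
            "auc_band": interpret_auc(pooled.auc),
            "pplr_band": interpret_lr(pooled.pplr, pooled.pnlr)[0],
            "pnlr_band": interpret_lr(pooled.pplr, pooled.pnlr)[1],
        },
        "higgins_i2": higgins,
        "deeks": deeks.to_dict() if deeks else None,
        "sroc_curve": {"fpr": fpr.tolist(), "sens": sens.tolist()},
        "studies_retained": [record_to_dict(r) for r in kept_records],
    }


def run_step1(
    studies: Sequence[Study2x2Record],
    quadas: Sequence[lmbp.QuadasAssessment],
    *,
    seed: int = bv.MC_SEED,
    alpha: float = 0.05,
) -> dict:
    """Step 1: applicability filter → per-biomarker fits, LMBP verdicts,
    pairwise comparisons, outlier and publication-bias diagnostics."""
    by_marker: dict[str, list[Study2x2Record]] = {}
    for r in studies:
        by_marker.setdefault(r.biomarker, []).append(r)
    quadas_by_id = {q.study_id: q for q in quadas}

    bundle: dict = {
        "step": 1,
        "seed": seed,
        "alpha": alpha,
        "biomarkers": {},
        "excluded_biomarkers": {},
        "comparisons": [],
        "lmbp": {},
    }

    surviving: dict[str, list] = {}
    for marker, recs in sorted(by_marker.items()):
        try:
            corrected = [apply_continuity_correction(r) for r in recs]
            accs = [study_accuracy(r) for r in corrected]
            decision = lmbp.clinical_applicability_filter(
                [(None, a.plr, a.nlr) for a in accs], marker
            )
            appraisals = [
                lmbp.appraise(quadas_by_id[a.study_id], a.plr, a.nlr)
                for a in accs
                if a.study_id in quadas_by_id
            ]
            bundle["lmbp"][marker] = {
                "verdict": lmbp.grade_biomarker(marker, appraisals).to_dict(),
                "appraisals": [asdict(a) for a in appraisals],
            }
            if not decision.keep:
                bundle["excluded_biomarkers"][marker] = decision.reason
                continue
            entry = _analyse_biomarker(marker, recs, seed=seed)
            entry["applicability"] = asdict(decision)
            bundle["biomarkers"][marker] = entry
            surviving[marker] = accs
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            if isinstance(exc, PipelineError):
                raise
            raise PipelineError("step1", f"biomarker {marker}", exc) from exc

    for m1, m2 in itertools.combinations(sorted(surviving), 2):
        try:
            accs = surviving[m1] + surviving[m2]
            ind = [True] * len(surviving[m1]) + [False] * len(surviving[m2])
            cmp_res = bv.compare_groups(accs, ind, label=f"{m1}_vs_{m2}", seed=seed)
            bundle["comparisons"].append(cmp_res.to_dict())
        except bv.FitError:
            bundle["comparisons"].append(
                {"label": f"{m1}_vs_{m2}", "error": "comparison not estimable"}
            )
    return _jsonable(bundle)


def run_step2(
    cohort: Sequence[vr.PatientRecord],
    *,
    seed: int = bv.MC_SEED,
    biomarkers: Sequence[str] | None = None,
) -> tuple[dict, list[Study2x2Record]]:
    """Step 2: cohort statistics plus experimental 2×2 rows for step 3."""
    vr.validate_cohort(cohort)
    markers = list(biomarkers) if biomarkers else [
        b for b in vr.KIT_CUTOFFS if any(b in r.biomarker_values for r in cohort)
    ]
    bundle: dict = {"step": 2, "seed": seed, "biomarkers": {}, "combinations": [],
                    "auc_comparisons": [], "strata": {}}
    aucs: dict[str, vr.AUCEstimate] = {}

    pairs: dict[str, dict[str, vr.PatientRecord]] = {}
    for r in cohort:
        pairs.setdefault(r.pair_id, {})[r.group] = r

    experimental: list[Study2x2Record] = []
    for marker in markers:
        case_v, ctrl_v = [], []
        for p in pairs.values():
            if "case" in p and "control" in p and marker in p["case"].biomarker_values and marker in p["control"].biomarker_values:
                case_v.append(p["case"].biomarker_values[marker])
                ctrl_v.append(p["control"].biomarker_values[marker])
        stat, pval, info = vr.paired_group_test(case_v, ctrl_v)
        values = [r.biomarker_values[marker] for r in cohort if marker in r.biomarker_values]
        labels = [r.group for r in cohort if marker in r.biomarker_values]
        est = vr.empirical_auc(values, labels)
        aucs[marker] = est
        rec, excluded = vr.cohort_to_2x2(cohort, marker)
        experimental.append(rec)
        bundle["biomarkers"][marker] = {
            "auc": est.to_dict(),
            "auc_band": interpret_auc(est.auc),
            "paired_test": {"statistic": stat, "p": pval, **info},
            "experimental_2x2": record_to_dict(rec),
            "excluded_subjects": excluded,
        }

    for m1, m2 in itertools.combinations(markers, 2):
        z, p = vr.compare_auc_independent(aucs[m1], aucs[m2])
        bundle["auc_comparisons"].append({"pair": f"{m1}_vs_{m2}", "z": z, "p": p})

    for size in (2, 3, 4):
        for subset in itertools.combinations(markers, size):
            try:
                frame, labels = vr.cohort_frame(cohort, subset)
                combo = vr.combine_biomarkers(frame, labels, subset)
            except ValueError:
                continue
            bundle["combinations"].append(
                {
                    "biomarkers": list(subset),
                    "auc": combo.auc.to_dict(),
                    "auc_band": interpret_auc(combo.auc.auc),
                    "ridge_fallback": combo.ridge_fallback,
                }
            )

    for marker in markers:
        strata_entry = {}
        for stratum in ("stage", "histology", "age", "control_type"):
            per_level = vr.stratified_auc(cohort, marker, stratum)
            level_dict = {k: v.to_dict() for k, v in per_level.items()}
            comps = []
            for l1, l2 in itertools.combinations(per_level, 2):
                z, p = vr.compare_auc_independent(per_level[l1], per_level[l2])
                comps.append({"pair": f"{l1}_vs_{l2}", "z": z, "p": p})
            strata_entry[stratum] = {"levels": level_dict, "comparisons": comps}
        bundle["strata"][marker] = strata_entry

    return _jsonable(bundle), experimental


def run_step3(
    step1_bundle: Mapping,
    experimental: Sequence[Study2x2Record],
    *,
    seed: int = bv.MC_SEED,
) -> dict:
    """Step 3: integrate experimental 2×2 rows into the outlier-excluded
    study sets, refit, and run subgroup / threshold-effect / bias diagnostics.

    Subgroup analyses fire for a biomarker when either component's Higgins
    I² exceeds 50%, flagging heterogeneity worth explaining.
    """
    by_marker_exp: dict[str, list[Study2x2Record]] = {}
    for r in experimental:
        by_marker_exp.setdefault(r.biomarker, []).append(r)

    bundle: dict = {"step": 3, "seed": seed, "biomarkers": {}, "subgroups": {}}
    for marker, entry in step1_bundle["biomarkers"].items():
        try:
            base = [record_from_dict(d) for d in entry["studies_retained"]]
            base_ids = {r.study_id for r in base}
            extra = by_marker_exp.get(marker, [])
            for r in extra:
                if r.study_id in base_ids:
                    raise ValueError(f"duplicate study_id {r.study_id!r}")
            combined = base + list(extra)
            res = _analyse_biomarker(marker, combined, seed=seed, exclude_outliers=False)
            res["n_experimental_rows"] = len(extra)
            heterogeneous = max(res["higgins_i2"].values()) > HIGGINS_SUBGROUP_TRIGGER
            res["subgroup_analysis_triggered"] = bool(heterogeneous)
            bundle["biomarkers"][marker] = res

            sub_entry = {}
            if heterogeneous:
                corrected = [apply_continuity_correction(r) for r in combined]
                accs = [study_accuracy(r) for r in corrected]
                for cov in ("pct_late_stage", "assay_method", "control_composition"):
                    try:
                        cmp_res = bv.subgroup_analysis(combined, accs, cov, seed=seed)
                        sub_entry[cov] = cmp_res.to_dict()
                    except (bv.FitError, ValueError) as exc:
                        sub_entry[cov] = {"error": str(exc)}
            bundle["subgroups"][marker] = sub_entry
        except Exception as exc:  # noqa: BLE001
            if isinstance(exc, (PipelineError, ValueError)):
                raise
            raise PipelineError("step3", f"biomarker {marker}", exc) from exc
    return _jsonable(bundle)


# ---------------------------------------------------------------------------
# Tabular exports (published-table shapes)


def pooled_accuracy_table(bundle: Mapping) -> pd.DataFrame:
    """Pooled-accuracy rows (Se/Sp/PLR/NLR/DOR/AUC, I², TE%, PB) per biomarker."""
    rows = []
    for marker, entry in bundle["biomarkers"].items():
        p = entry["pooled"]
        deeks = entry.get("deeks") or {}
        rows.append(
            {
                "biomarker": marker,
                "pooled_sens": p["pooled_sens"],
                "sens_lo": p["sens_lo"],
                "sens_hi": p["sens_hi"],
                "pooled_spec": p["pooled_spec"],
                "spec_lo": p["spec_lo"],
                "spec_hi": p["spec_hi"],
                "pplr": p["pplr"],
                "pplr_lo": p["pplr_lo"],
                "pplr_hi": p["pplr_hi"],
                "pnlr": p["pnlr"],
                "pnlr_lo": p["pnlr_lo"],
                "pnlr_hi": p["pnlr_hi"],
                "pdor": p["pdor"],
                "pdor_lo": p["pdor_lo"],
                "pdor_hi": p["pdor_hi"],
                "auc": p["auc"],
                "auc_lo": p["auc_lo"],
                "auc_hi": p["auc_hi"],
                "bivariate_i2_pct": p["bivariate_i2"],
                "threshold_effect_pct": p["threshold_effect_pct"],
                "deeks_p": deeks.get("slope_p"),
                "publication_bias": deeks.get("biased"),
                "auc_band": entry["interpretation"]["auc_band"],
                "pplr_band": entry["interpretation"]["pplr_band"],
                "pnlr_band": entry["interpretation"]["pnlr_band"],
            }
        )
    return pd.DataFrame(rows)


def subgroup_table(bundle: Mapping) -> pd.DataFrame:
    """Subgroup-comparison rows (relative Se/Sp, p-values, global p)."""
    rows = []
    for marker, subs in bundle.get("subgroups", {}).items():
        for cov, res in subs.items():
            if "error" in res:
                rows.append({"biomarker": marker, "covariate": cov, "error": res["error"]})
                continue
            rows.append(
                {
                    "biomarker": marker,
                    "covariate": cov,
                    "label": res["label"],
                    "relative_sensitivity": res["relative_sensitivity"],
                    "rel_sens_lo": res["rel_sens_lo"],
                    "rel_sens_hi": res["rel_sens_hi"],
                    "sens_p": res["p_sens"],
                    "relative_specificity": res["relative_specificity"],
                    "rel_spec_lo": res["rel_spec_lo"],
                    "rel_spec_hi": res["rel_spec_hi"],
                    "spec_p": res["p_spec"],
                    "global_p": res["p_global"],
                }
            )
    return pd.DataFrame(rows)


def render_report(bundle: Mapping) -> str:
    """Human-readable summary; every number is read from the bundle."""
    lines = [f"=== Pipeline step {bundle.get('step')} report (seed {bundle.get('seed')}) ==="]
    for marker, entry in bundle.get("biomarkers", {}).items():
        p = entry["pooled"]
        interp = entry["interpretation"]
        lines.append(
            f"{marker}: Se {p['pooled_sens']:.2f} ({p['sens_lo']:.2f}-{p['sens_hi']:.2f})"
            f"  Sp {p['pooled_spec']:.2f} ({p['spec_lo']:.2f}-{p['spec_hi']:.2f})"
            f"  PLR {p['pplr']:.1f}  NLR {p['pnlr']:.2f}"
            f"  AUC {p['auc']:.2f} [{interp['auc_band']}]"
            f"  I2 {p['bivariate_i2']:.0f}%  TE {p['threshold_effect_pct']:.0f}%"
        )
        deeks = entry.get("deeks")
        if deeks:
            lines.append(
                f"  Deeks p={deeks['slope_p']:.2f} "
                f"({'publication bias' if deeks['biased'] else 'no publication bias'})"
            )
    for marker, verdict in bundle.get("lmbp", {}).items():
        v = verdict["verdict"]
        lines.append(f"LMBP {marker}: {v['strength']} -> {v['recommendation']}")
    for cmp_res in bundle.get("comparisons", []):
        if "error" in cmp_res:
            lines.append(f"compare {cmp_res['label']}: {cmp_res['error']}")
        else:
            lines.append(
                f"compare {cmp_res['label']}: rel Se {cmp_res['relative_sensitivity']:.2f}"
                f" (p={cmp_res['p_sens']:.3f}), rel Sp {cmp_res['relative_specificity']:.2f}"
                f" (p={cmp_res['p_spec']:.3f}), global p={cmp_res['p_global']:.3f}"
            )
    for marker, subs in bundle.get("subgroups", {}).items():
        for cov, res in subs.items():
            if "error" in res:
                continue
            lines.append(
                f"subgroup {marker}/{res['label']}: rel Se {res['relative_sensitivity']:.2f}"
                f" (p={res['p_sens']:.3f}), rel Sp {res['relative_specificity']:.2f}"
                f" (p={res['p_spec']:.3f}), global p={res['p_global']:.3f}"
            )
    return "\n".join(lines)
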