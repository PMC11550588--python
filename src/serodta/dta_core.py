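"""Study-level 2×2 diagnostic accuracy data and closed-form per-study statistics.

A diagnostic test accuracy (DTA) study cross-classifies subjects by true
disease state (from a reference standard) and index-test result, yielding a
2×2 table of true positives (TP), false positives (FP), false negatives (FN)
and true negatives (TN).  From that table this module computes sensitivity,
specificity, the positive/negative likelihood ratios, the diagnostic odds
ratio, and logit-scale Wald 95% confidence intervals — the per-study
quantities every downstream meta-analytic step consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

Z95 = float(norm.ppf(0.975))

CONTROL_COMPOSITIONS = frozenset({"healthy", "benign", "mixed", "unknown"})
ASSAY_METHODS = frozenset({"CLIA", "ELISA", "RIA", "other", "unknown"})
DESIGNS = frozenset({"case_control", "cohort", "unknown"})

#: column order of the study-level CSV interface
STUDY_CSV_COLUMNS = [
    "study_id",
    "biomarker",
    "tp",
    "fp",
    "fn",
    "tn",
    "control_composition",
    "pct_late_stage",
    "assay_method",
    "design",
]


class InvalidStudyError(ValueError):
    """Raised when a 2×2 record violates its invariants."""


def round_half_up(x: float, decimals: int) -> float:
    """Round ``x`` half-up to ``decimals`` places (presentation-layer rule).

    Python's built-in ``round`` is banker's rounding; published accuracy
    tables use conventional half-up rounding, so reproduction of printed
    values needs an explicit rule applied once, at the very end.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Study2x2Record:
    """One study × biomarker arm: four counts plus covariates.

    ``pct_late_stage`` is the proportion of cases with stage III/IV tumors
    (``None`` when unreported).  ``corrected`` marks tables to which the
    zero-cell continuity correction has been applied; counts must be
    integers before correction.
    """

    study_id: str
    biomarker: str
    tp: float
    fp: float
    fn: float
    tn: float
    control_composition: str = "unknown"
    pct_late_stage: float | None = None
    assay_method: str = "unknown"
    design: str = "case_control"
    extra_covariates: Mapping[str, object] = field(default_factory=dict)
    corrected: bool = False

    def __post_init__(self) -> None:
        if not self.biomarker:
            raise InvalidStudyError("biomarker label must be non-empty")
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise InvalidStudyError(
                    f"{self.study_id}: count {name}={v} must be a finite non-negative number"
                )
            if not self.corrected and float(v) != int(v):
                raise InvalidStudyError(
                    f"{self.study_id}: count {name}={v} must be an integer before correction"
                )
        if self.tp + self.fn < 1 or self.tn + self.fp < 1:
            raise InvalidStudyError(
                f"{self.study_id}: needs at least one diseased and one non-diseased subject"
            )
        if self.control_composition not in CONTROL_COMPOSITIONS:
            raise InvalidStudyError(
                f"{self.study_id}: control_composition {self.control_composition!r} "
                f"not one of {sorted(CONTROL_COMPOSITIONS)}"
            )
        if self.assay_method not in ASSAY_METHODS:
            raise InvalidStudyError(
                f"{self.study_id}: assay_method {self.assay_method!r} not one of {sorted(ASSAY_METHODS)}"
            )
        if self.design not in DESIGNS:
            raise InvalidStudyError(f"{self.study_id}: design {self.design!r} invalid")
        if self.pct_late_stage is not None and not 0.0 <= self.pct_late_stage <= 1.0:
            raise InvalidStudyError(
                f"{self.study_id}: pct_late_stage must lie in [0, 1] or be missing"
            )

    @property
    def n_diseased(self) -> float:
        return self.tp + self.fn

    @property
    def n_nondiseased(self) -> float:
        return self.tn + self.fp


@dataclass(frozen=True)
class StudyAccuracy:
    """Per-study accuracy statistics with logit-scale Wald 95% intervals."""

    study_id: str
    biomarker: str
    sens: float
    spec: float
    plr: float
    nlr: float
    dor: float
    logit_sens: float
    logit_spec: float
    se_logit_sens: float
    se_logit_spec: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]
    plr_ci: tuple[float, float]
    nlr_ci: tuple[float, float]
    dor_ci: tuple[float, float]
    corrected: bool


def apply_continuity_correction(record: Study2x2Record) -> Study2x2Record:
    """Add 0.5 to all four cells of a table containing any zero cell.

    The correction is applied per affected table only — not dataset-wide —
    and the result is flagged ``corrected=True`` for audit.  Tables without
    zero cells pass through unchanged.
    """
    cells = (record.tp, record.fp, record.fn, record.tn)
    if all(c == 0 for c in cells):
        raise InvalidStudyError(f"{record.study_id}: all four cells are zero")
    if any(c == 0 for c in cells):
        return replace(
            record,
            tp=record.tp + 0.5,
            fp=record.fp + 0.5,
            fn=record.fn + 0.5,
            tn=record.tn + 0.5,
            corrected=True,
        )
    return record


def study_accuracy(record: Study2x2Record) -> StudyAccuracy:
    """Compute per-study sensitivity/specificity/LR/DOR with 95% CIs.

    The record must already have passed :func:`apply_continuity_correction`,
    so every cell is strictly positive and no proportion can be exactly 0
    or 1.  Intervals for sensitivity and specificity are Wald on the logit
    scale; likelihood-ratio and DOR intervals are Wald on the log scale with
    the standard count-based variance formulas.
    """
    corrected = apply_continuity_correction(record)
    if corrected is not record:
        raise InvalidStudyError(
            f"{record.study_id}: contains zero cells; apply the continuity correction first"
        )
    tp, fp, fn, tn = record.tp, record.fp, record.fn, record.tn
    n1, n0 = tp + fn, tn + fp
    sens = tp / n1
    spec = tn / n0
    assert 0.0 < sens < 1.0 and 0.0 < spec < 1.0, (
        f"{record.study_id}: degenerate proportion after correction"
    )
    lsens, lspec = float(logit(sens)), float(logit(spec))
    se_lsens = math.sqrt(1.0 / tp + 1.0 / fn)
    se_lspec = math.sqrt(1.0 / tn + 1.0 / fp)
    plr = sens / (1.0 - spec)
    nlr = (1.0 - sens) / spec
    dor = plr / nlr

    se_ln_plr = math.sqrt(1.0 / tp - 1.0 / n1 + 1.0 / fp - 1.0 / n0)
    se_ln_nlr = math.sqrt(1.0 / fn - 1.0 / n1 + 1.0 / tn - 1.0 / n0)
    se_ln_dor = math.sqrt(1.0 / tp + 1.0 / fp + 1.0 / fn + 1.0 / tn)

    def _expit_ci(center: float, se: float) -> tuple[float, float]:
        return float(expit(center - Z95 * se)), float(expit(center + Z95 * se))

    def _log_ci(point: float, se: float) -> tuple[float, float]:
        return point * math.exp(-Z95 * se), point * math.exp(Z95 * se)

    return StudyAccuracy(
        study_id=record.study_id,
        biomarker=record.biomarker,
        sens=sens,
        spec=spec,
        plr=plr,
        nlr=nlr,
        dor=dor,
        logit_sens=lsens,
        logit_spec=lspec,
        se_logit_sens=se_lsens,
        se_logit_spec=se_lspec,
        sens_ci=_expit_ci(lsens, se_lsens),
        spec_ci=_expit_ci(lspec, se_lspec),
        plr_ci=_log_ci(plr, se_ln_plr),
        nlr_ci=_log_ci(nlr, se_ln_nlr),
        dor_ci=_log_ci(dor, se_ln_dor),
        corrected=record.corrected,
    )


def lr_from_sens_spec(sens: float, spec: float, decimals: int) -> tuple[float, float]:
    """Likelihood ratios from pooled sensitivity/specificity, rounded half-up.

    This is the arithmetic behind published accuracy tables: PLR =
    sens/(1−spec), NLR = (1−sens)/spec, each rounded to ``decimals``.
    """
    if not (0.0 < sens < 1.0 and 0.0 < spec < 1.0):
        raise ValueError("sens and spec must lie strictly inside (0, 1)")
    plr = sens / (1.0 - spec)
    nlr = (1.0 - sens) / spec
    return round_half_up(plr, decimals), round_half_up(nlr, decimals)


def dor_from_lrs(plr: float, nlr: float, decimals: int) -> float:
    """Diagnostic odds ratio PLR/NLR, rounded half-up to ``decimals``."""
    if plr <= 0 or nlr <= 0:
        raise ValueError("likelihood ratios must be positive")
    return round_half_up(plr / nlr, decimals)


# ---------------------------------------------------------------------------
# CSV interface


def _record_from_row(row: Mapping[str, object]) -> Study2x2Record:
    def _clean(v, default):
        if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
            return default
        return v

    pct = _clean(row.get("pct_late_stage"), None)
    return Study2x2Record(
        study_id=str(row["study_id"]),
        biomarker=str(row["biomarker"]),
        tp=float(row["tp"]),
        fp=float(row["fp"]),
        fn=float(row["fn"]),
        tn=float(row["tn"]),
        control_composition=str(_clean(row.get("control_composition"), "unknown")),
        pct_late_stage=None if pct is None else float(pct),
        assay_method=str(_clean(row.get("assay_method"), "unknown")),
        design=str(_clean(row.get("design"), "unknown")),
    )


def read_studies_csv(path) -> list[Study2x2Record]:
    """Parse the study-level CSV interface (blank covariate cells = unknown)."""
    df = pd.read_csv(path, dtype={"study_id": str, "biomarker": str}, float_precision="round_trip")
    missing = [c for c in ("study_id", "biomarker", "tp", "fp", "fn", "tn") if c not in df.columns]
    if missing:
        raise InvalidStudyError(f"studies CSV missing required columns: {missing}")
    return [_record_from_row(row) for row in df.to_dict(orient="records")]


def write_studies_csv(records: list[Study2x2Record], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "study_id": r.study_id,
                "biomarker": r.biomarker,
                "tp": r.tp,
                "fp": r.fp,
                "fn": r.fn,
                "tn": r.tn,
                "control_composition": "" if r.control_composition == "unknown" else r.control_composition,
                "pct_late_stage": "" if r.pct_late_stage is None else repr(float(r.pct_late_stage)),
                "assay_method": "" if r.assay_method == "unknown" else r.assay_method,
                "design": "" if r.design == "unknown" else r.design,
            }
        )
    pd.DataFrame(rows, columns=STUDY_CSV_COLUMNS).to_csv(path, index=False)


def accuracy_table(records: list[Study2x2Record]) -> pd.DataFrame:
    """Per-study accuracy table with every :class:`StudyAccuracy` field.

    Values are full precision; use ``float_format='%.4f'`` when writing the
    4-decimal fixed CSV.
    """
    rows = []
    for rec in records:
        acc = study_accuracy(apply_continuity_correction(rec))
        rows.append(
            {
                "study_id": acc.study_id,
                "biomarker": acc.biomarker,
                "sens": acc.sens,
                "spec": acc.spec,
                "plr": acc.plr,
                "nlr": acc.nlr,
                "dor": acc.dor,
                "logit_sens": acc.logit_sens,
                "logit_spec": acc.logit_spec,
                "se_logit_sens": acc.se_logit_sens,
                "se_logit_spec": acc.se_logit_spec,
                "sens_lo": acc.sens_ci[0],
                "sens_hi": acc.sens_ci[1],
                "spec_lo": acc.spec_ci[0],
                "spec_hi": acc.spec_ci[1],
                "plr_lo": acc.plr_ci[0],
                "plr_hi": acc.plr_ci[1],
                "nlr_lo": acc.nlr_ci[0],
                "nlr_hi": acc.nlr_ci[1],
                "dor_lo": acc.dor_ci[0],
                "dor_hi": acc.dor_ci[1],
                "corrected": acc.corrected,
            }
        )
    return pd.DataFrame(rows)


def write_accuracy_csv(records: list[Study2x2Record], path) -> None:
    accuracy_table(records).to_csv(path, index=False, float_format="%.4f")
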