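"""Laboratory Medicine Best Practices (LMBP) evidence grading.

The LMBP framework (a CDC initiative) turns a body of diagnostic-accuracy
studies into a practice recommendation in two steps.  "Apprizing" rates each
study on (a) methodological quality, by scoring the seven QUADAS-2 domains
(1 for low risk of bias, 0.5 for unclear, 0 for high; good > 5, fair
3.5–5, poor ≤ 3) and (b) effect size, from its likelihood-ratio pair
(substantial: LR+ > 10 and LR− < 0.1; moderate: exactly one of the two;
minimal: neither).  "Analyzing" tallies qualifying studies into an overall
evidence strength (High / Moderate / Suggestive / Insufficient) which maps
onto the recommendation categories recommend / no recommendation /
recommend against.

An upstream clinical-applicability filter decides which biomarkers enter
the meta-analysis at all: at least four studies, of which more than half
show AUC > 0.70 and/or LR+ > 2 with LR− < 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

RISK_DOMAINS = (
    "risk_patient_selection",
    "risk_index_test",
    "risk_reference_standard",
    "risk_flow_timing",
)
APPLICABILITY_DOMAINS = (
    "appl_patient_selection",
    "appl_index_test",
    "appl_reference_standard",
)
ALL_DOMAINS = RISK_DOMAINS + APPLICABILITY_DOMAINS

RATINGS = ("low", "unclear", "high")
_DOMAIN_POINTS = {"low": 1.0, "unclear": 0.5, "high": 0.0}

QUADAS_CSV_COLUMNS = ("study_id",) + ALL_DOMAINS


@dataclass(frozen=True)
class QuadasAssessment:
    """QUADAS-2 ratings for one study: four risk-of-bias + three applicability domains."""

    study_id: str
    ratings: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = [d for d in ALL_DOMAINS if d not in self.ratings]
        if missing:
            raise ValueError(f"{self.study_id}: missing QUADAS-2 domains {missing}")
        bad = {d: r for d, r in self.ratings.items() if r not in RATINGS}
        if bad:
            raise ValueError(f"{self.study_id}: invalid ratings {bad}")
        if len(self.ratings) != 7:
            raise ValueError(f"{self.study_id}: expected exactly 7 domain ratings")


@dataclass(frozen=True)
class LMBPAppraisal:
    """Per-study Apprizing result: quality score/rating plus effect-size class."""

    study_id: str
    quality_score: float
    quality_rating: str  # good | fair | poor
    effect_size_class: str  # substantial | moderate | minimal


@dataclass
class EvidenceVerdict:
    biomarker: str
    strength: str  # High | Moderate | Suggestive | Insufficient
    recommendation: str  # recommend | no_recommendation | recommend_against
    audit_trail: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "biomarker": self.biomarker,
            "strength": self.strength,
            "recommendation": self.recommendation,
            "audit_trail": list(self.audit_trail),
        }


def quadas_quality_score(assessment: QuadasAssessment) -> tuple[float, str]:
    """Score the 7 QUADAS-2 domains and band into good / fair / poor.

    low → 1, unclear → 0.5, high → 0 per domain; rating good if score > 5,
    fair if 3.5 ≤ score ≤ 5, poor if score ≤ 3.  Scores come in 0.5 steps so
    the (3, 3.5) band gap can never be hit.
    """
    score = sum(_DOMAIN_POINTS[assessment.ratings[d]] for d in ALL_DOMAINS)
    if score > 5.0:
        rating = "good"
    elif score >= 3.5:
        rating = "fair"
    else:
        rating = "poor"
    return score, rating


def effect_size_class(plr: float, nlr: float) -> str:
    """LMBP effect-size class from the likelihood-ratio pair.

    substantial iff LR+ > 10 and LR− < 0.1; moderate iff exactly one of the
    two criteria holds; minimal otherwise (boundary values fail their
    criterion, matching the strict inequalities of the rule).
    """
    if plr <= 0 or nlr <= 0:
        raise ValueError("likelihood ratios must be positive")
    strong_plr = plr > 10.0
    strong_nlr = nlr < 0.1
    if strong_plr and strong_nlr:
        return "substantial"
    if strong_plr or strong_nlr:
        return "moderate"
    return "minimal"


def appraise(assessment: QuadasAssessment, plr: float, nlr: float) -> LMBPAppraisal:
    score, rating = quadas_quality_score(assessment)
    return LMBPAppraisal(
        study_id=assessment.study_id,
        quality_score=score,
        quality_rating=rating,
        effect_size_class=effect_size_class(plr, nlr),
    )


_QUALITY_ORDER = {"poor": 0, "fair": 1, "good": 2}
_EFFECT_ORDER = {"minimal": 0, "moderate": 1, "substantial": 2}


def evidence_strength(
    appraisals: Sequence[LMBPAppraisal],
    *,
    count_higher_tiers: bool = True,
    audit: list[str] | None = None,
) -> str:
    """Summarize per-study appraisals into overall evidence strength.

    Tiers are evaluated top-down: High needs ≥3 (substantial, good) studies;
    Moderate ≥2 (substantial, good) or ≥3 (moderate+, good); Suggestive ≥1
    (substantial, good), ≥2 (moderate+, good) or ≥3 (moderate+, fair+);
    anything else is Insufficient.  With ``count_higher_tiers`` (default),
    substantial-effect studies count toward moderate-effect tallies and good
    quality toward fair tallies, which makes the rule exhaustive; set False
    for the literal, exact-category reading.
    """
    trail = audit if audit is not None else []

    def n_at_least(effect: str, quality: str, exact: bool = False) -> int:
        if exact or not count_higher_tiers:
            return sum(
                1
                for a in appraisals
                if a.effect_size_class == effect and a.quality_rating == quality
            )
        return sum(
            1
            for a in appraisals
            if _EFFECT_ORDER[a.effect_size_class] >= _EFFECT_ORDER[effect]
            and _QUALITY_ORDER[a.quality_rating] >= _QUALITY_ORDER[quality]
        )

    n_sub_good = n_at_least("substantial", "good")
    n_mod_good = n_at_least("moderate", "good")
    n_mod_fair = n_at_least("moderate", "fair")

    if n_sub_good >= 3:
        trail.append(f"High: {n_sub_good} substantial+good studies (>=3)")
        return "High"
    if n_sub_good >= 2:
        trail.append(f"Moderate: {n_sub_good} substantial+good studies (>=2)")
        return "Moderate"
    if n_mod_good >= 3:
        trail.append(f"Moderate: {n_mod_good} moderate-or-better+good studies (>=3)")
        return "Moderate"
    if n_sub_good >= 1:
        trail.append(f"Suggestive: {n_sub_good} substantial+good study (>=1)")
        return "Suggestive"
    if n_mod_good >= 2:
        trail.append(f"Suggestive: {n_mod_good} moderate-or-better+good studies (>=2)")
        return "Suggestive"
    if n_mod_fair >= 3:
        trail.append(f"Suggestive: {n_mod_fair} moderate-or-better+fair-or-better studies (>=3)")
        return "Suggestive"
    trail.append(
        f"Insufficient: counts substantial+good={n_sub_good}, "
        f"moderate+good={n_mod_good}, moderate+fair={n_mod_fair}"
    )
    return "Insufficient"


def recommendation(strength: str) -> str:
    """Map evidence strength to the LMBP recommendation category.

    High/Moderate → recommend; Suggestive/Insufficient → no recommendation.
    ``recommend_against`` is reserved for an adverse-effects flag and is
    never fired automatically.
    """
    if strength in ("High", "Moderate"):
        return "recommend"
    if strength in ("Suggestive", "Insufficient"):
        return "no_recommendation"
    raise ValueError(f"unknown evidence strength {strength!r}")


def grade_biomarker(
    biomarker: str,
    appraisals: Sequence[LMBPAppraisal],
    *,
    count_higher_tiers: bool = True,
) -> EvidenceVerdict:
    """Full Analyzing step for one biomarker, with an audit trail."""
    trail: list[str] = [f"{len(appraisals)} appraised studies"]
    strength = evidence_strength(
        appraisals, count_higher_tiers=count_higher_tiers, audit=trail
    )
    rec = recommendation(strength)
    trail.append(f"recommendation: {rec}")
    return EvidenceVerdict(
        biomarker=biomarker, strength=strength, recommendation=rec, audit_trail=trail
    )


@dataclass
class ApplicabilityDecision:
    biomarker: str
    keep: bool
    reason: str
    n_studies: int
    n_qualifying: int


def clinical_applicability_filter(
    per_study_stats: Sequence[tuple[float | None, float, float]],
    biomarker: str,
) -> ApplicabilityDecision:
    """Keep a biomarker iff ≥4 studies and >50% of them qualify.

    A study qualifies when AUC > 0.70 (if reported) or its likelihood-ratio
    pair shows LR+ > 2 and LR− < 0.5.  Each tuple is (auc-or-None, plr, nlr).
    """
    if not per_study_stats:
        raise ValueError("at least one study is required")
    n = len(per_study_stats)
    n_q = 0
    for auc, plr, nlr in per_study_stats:
        if (auc is not None and auc > 0.70) or (plr > 2.0 and nlr < 0.5):
            n_q += 1
    if n < 4:
        return ApplicabilityDecision(
            biomarker, False, "fewer than four studies", n, n_q
        )
    if n_q * 2 <= n:  # strictly more than 50% must qualify
        return ApplicabilityDecision(
            biomarker,
            False,
            f"only {n_q}/{n} studies meet AUC>0.70 or (LR+>2 and LR-<0.5)",
            n,
            n_q,
        )
    return ApplicabilityDecision(biomarker, True, "clinically applicable", n, n_q)


# ---------------------------------------------------------------------------
# CSV interface


def read_quadas_csv(path) -> list[QuadasAssessment]:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in QUADAS_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"QUADAS CSV missing columns: {missing}")
    return [
        QuadasAssessment(
            study_id=row["study_id"],
            ratings={d: row[d] for d in ALL_DOMAINS},
        )
        for row in df.to_dict(orient="records")
    ]


def write_quadas_csv(assessments: Sequence[QuadasAssessment], path) -> None:
    rows = [
        {"study_id": a.study_id, **{d: a.ratings[d] for d in ALL_DOMAINS}}
        for a in assessments
    ]
    pd.DataFrame(rows, columns=list(QUADAS_CSV_COLUMNS)).to_csv(path, index=False)
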