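"""Seeded generators for study-level 2×2 datasets, matched cohorts and QUADAS fixtures.

All generators are pure functions of (config, seed): one global seed fans
out into named substreams so that adding a biomarker or component never
perturbs the draws of another.  The study-level generator follows exactly
the data-generating process the bivariate model assumes — a bivariate
logit-normal between-study law with binomial within-study sampling — and the
cohort generator produces 1:1 sex/age-matched pairs with log-normal
biomarker levels whose case shift is set from a target AUC through the
binormal identity AUC = Φ(δ/(σ√2)).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, logit
from scipy.stats import norm

from .dta_core import Study2x2Record
from .lmbp import ALL_DOMAINS, QuadasAssessment
from .validation import PatientRecord


def substream(seed: int, *keys: str) -> np.random.Generator:
    """Deterministic named child stream of a global seed."""
    spawn_key = tuple(zlib.crc32(k.encode()) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


class ConfigError(ValueError):
    """Raised with the list of offending config fields."""


# ---------------------------------------------------------------------------
# Study-level meta-analysis data


@dataclass
class MetaSimConfig:
    """Data-generating parameters for one biomarker's study set.

    ``covariate_effects`` maps a study-level condition to a logit shift on
    one accuracy component; supported conditions are ``late_majority``
    (study has >50% late-stage cases), ``clia`` and ``benign_controls``.
    Each value is ``(component, shift)`` with component 'sens' or 'spec';
    shifts are applied centered (±shift/2 around the configured mean) so the
    marginal pooled accuracy stays at the configured truth.
    """

    biomarker: str
    n_studies: int = 20
    true_sens: float = 0.73
    true_spec: float = 0.83
    tau2_sens: float = 0.2
    tau2_spec: float = 0.2
    rho: float = -0.3
    case_size_range: tuple[int, int] = (40, 200)
    control_size_range: tuple[int, int] = (40, 200)
    covariate_effects: Mapping[str, tuple[str, float]] = field(default_factory=dict)
    prob_late_majority: float = 0.5
    prob_clia: float = 0.6
    prob_benign: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if self.n_studies < 1:
            bad.append("n_studies")
        for name in ("true_sens", "true_spec"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                bad.append(name)
        for name in ("tau2_sens", "tau2_spec"):
            if getattr(self, name) < 0:
                bad.append(name)
        if not -1.0 <= self.rho <= 1.0:
            bad.append("rho")
        for name in ("case_size_range", "control_size_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                bad.append(name)
        for cond, eff in self.covariate_effects.items():
            if cond not in ("late_majority", "clia", "benign_controls") or eff[0] not in ("sens", "spec"):
                bad.append(f"covariate_effects[{cond}]")
        if bad:
            raise ConfigError(f"invalid MetaSimConfig fields: {bad}")


def simulate_dta_studies(config: MetaSimConfig) -> list[Study2x2Record]:
    """Draw study-level 2×2 tables from the bivariate logit-normal model.

    Per study: the (logit sens, logit spec) pair is bivariate normal around
    the configured means (plus any centered covariate shifts); arm sizes are
    uniform over the configured ranges; TP ~ Binomial(n1, sens) and
    TN ~ Binomial(n0, spec).  Identical config+seed gives identical output.
    """
    config.validate()
    rng = substream(config.seed, "dta", config.biomarker)
    t1, t2 = config.tau2_sens, config.tau2_spec
    c = config.rho * math.sqrt(t1 * t2)
    T = np.array([[t1, c], [c, t2]])
    mu = np.array([logit(config.true_sens), logit(config.true_spec)])

    records = []
    for i in range(config.n_studies):
        late_major = bool(rng.random() < config.prob_late_majority)
        clia = bool(rng.random() < config.prob_clia)
        benign = bool(rng.random() < config.prob_benign)
        pct_late = float(
            rng.uniform(0.5, 0.95) if late_major else rng.uniform(0.05, 0.5)
        )
        shift = np.zeros(2)
        flags = {"late_majority": late_major, "clia": clia, "benign_controls": benign}
        for cond, (component, eff) in config.covariate_effects.items():
            j = 0 if component == "sens" else 1
            shift[j] += eff * (0.5 if flags[cond] else -0.5)
        eta = rng.multivariate_normal(mu + shift, T)
        se_i, sp_i = float(expit(eta[0])), float(expit(eta[1]))
        n1 = int(rng.integers(config.case_size_range[0], config.case_size_range[1] + 1))
        n0 = int(
            rng.integers(config.control_size_range[0], config.control_size_range[1] + 1)
        )
        tp = int(rng.binomial(n1, se_i))
        tn = int(rng.binomial(n0, sp_i))
        records.append(
            Study2x2Record(
                study_id=f"{config.biomarker}_study_{i + 1:03d}",
                biomarker=config.biomarker,
                tp=tp,
                fp=n0 - tn,
                fn=n1 - tp,
                tn=tn,
                control_composition="benign" if benign else "healthy",
                pct_late_stage=pct_late,
                assay_method="CLIA" if clia else "ELISA",
                design="case_control",
            )
        )
    return records


# ---------------------------------------------------------------------------
# Matched case-control cohort


@dataclass
class BiomarkerSimSpec:
    """Log-normal generating law for one biomarker in the cohort simulator.

    The case/control separation is set either directly (``log_shift``) or
    from ``target_auc`` via the binormal identity δ = √2·σ·Φ⁻¹(AUC).
    Covariate effects (log-scale, applied to cases, centered within the
    case population) plant the subgroup structure the validation step is
    meant to detect: e.g. larger shifts for LUSC/LLCC than LUAD, an age
    effect above 65, and an optional late-stage effect.
    """

    name: str
    control_log_mean: float
    log_sd: float = 1.0
    target_auc: float | None = 0.85
    log_shift: float | None = None
    stage_effect: float = 0.0
    histology_effects: Mapping[str, float] = field(default_factory=dict)
    age_effect: float = 0.0

    def delta(self) -> float:
        if self.log_shift is not None:
            return self.log_shift
        if self.target_auc is None or not 0.5 < self.target_auc < 1.0:
            raise ConfigError(f"{self.name}: target_auc must lie in (0.5, 1)")
        return math.sqrt(2.0) * self.log_sd * float(norm.ppf(self.target_auc))


@dataclass
class CohortSimConfig:
    """Matched-pair cohort layout: sizes, covariate mixes and per-marker laws."""

    n_pairs: int = 70
    biomarkers: Sequence[BiomarkerSimSpec] = field(default_factory=list)
    healthy_fraction: float = 0.5
    pct_late: float = 0.4
    histology_probs: Mapping[str, float] = field(
        default_factory=lambda: {"LUAD": 0.55, "LUSC": 0.40, "LLCC": 0.05}
    )
    age_range: tuple[int, int] = (40, 80)
    male_fraction: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if self.n_pairs < 2:
            bad.append("n_pairs")
        if not 0.0 <= self.healthy_fraction <= 1.0:
            bad.append("healthy_fraction")
        if not 0.0 <= self.pct_late <= 1.0:
            bad.append("pct_late")
        if abs(sum(self.histology_probs.values()) - 1.0) > 1e-9:
            bad.append("histology_probs")
        if self.age_range[0] > self.age_range[1]:
            bad.append("age_range")
        for spec in self.biomarkers:
            if spec.log_sd <= 0:
                bad.append(f"{spec.name}.log_sd")
        if bad:
            raise ConfigError(f"invalid CohortSimConfig fields: {bad}")


def simulate_patient_cohort(config: CohortSimConfig) -> list[PatientRecord]:
    """Generate 1:1 sex- and age-matched (±2 years) case/control pairs.

    Biomarker levels are log-normal; case levels add the configured (or
    AUC-derived) shift plus centered covariate effects.  Controls split
    into healthy and benign-lung-disease subjects per ``healthy_fraction``.
    """
    config.validate()
    rng = substream(config.seed, "cohort")
    n = config.n_pairs
    ages = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)
    sexes = np.where(rng.random(n) < config.male_fraction, "M", "F")
    stages = np.where(rng.random(n) < config.pct_late, "late", "early")
    hist_names = list(config.histology_probs)
    hist = rng.choice(hist_names, size=n, p=[config.histology_probs[h] for h in hist_names])
    n_healthy = int(round(config.healthy_fraction * n))
    control_types = np.array(["healthy"] * n_healthy + ["benign"] * (n - n_healthy))
    rng.shuffle(control_types)
    age_jitter = rng.integers(-2, 3, size=n)  # ±2-year matching window

    late_ind = (stages == "late").astype(float)
    old_ind = (ages > 65).astype(float)

    case_values: dict[str, np.ndarray] = {}
    ctrl_values: dict[str, np.ndarray] = {}
    for spec in config.biomarkers:
        brng = substream(config.seed, "cohort", spec.name)
        delta = spec.delta()
        hist_eff = np.array([spec.histology_effects.get(h, 0.0) for h in hist])
        # center planted effects so the marginal case mean stays at delta
        centered = (
            spec.stage_effect * (late_ind - late_ind.mean())
            + (hist_eff - hist_eff.mean())
            + spec.age_effect * (old_ind - old_ind.mean())
        )
        ctrl = np.exp(
            spec.control_log_mean + spec.log_sd * brng.standard_normal(n)
        )
        case = np.exp(
            spec.control_log_mean
            + delta
            + centered
            + spec.log_sd * brng.standard_normal(n)
        )
        case_values[spec.name] = case
        ctrl_values[spec.name] = ctrl

    records: list[PatientRecord] = []
    for i in range(n):
        pair = f"P{i + 1:03d}"
        records.append(
            PatientRecord(
                subject_id=f"{pair}_case",
                group="case",
                pair_id=pair,
                biomarker_values={b: float(case_values[b][i]) for b in case_values},
                age=float(ages[i]),
                sex=str(sexes[i]),
                stage=str(stages[i]),
                histology=str(hist[i]),
                control_type="none",
            )
        )
        ctrl_age = int(np.clip(ages[i] + age_jitter[i], config.age_range[0] - 2, config.age_range[1] + 2))
        records.append(
            PatientRecord(
                subject_id=f"{pair}_control",
                group="control",
                pair_id=pair,
                biomarker_values={b: float(ctrl_values[b][i]) for b in ctrl_values},
                age=float(ctrl_age),
                sex=str(sexes[i]),
                stage="none",
                histology="none",
                control_type=str(control_types[i]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# QUADAS-2 assessments


def simulate_quadas(
    n_studies: int,
    rating_probabilities: Mapping[str, tuple[float, float, float]] | tuple[float, float, float],
    seed: int,
    *,
    study_ids: Sequence[str] | None = None,
) -> list[QuadasAssessment]:
    """Independent categorical draws of (low, unclear, high) per domain.

    ``rating_probabilities`` is either one (p_low, p_unclear, p_high) triple
    used for every domain or a per-domain mapping; each triple must sum to 1.
    """
    if isinstance(rating_probabilities, tuple):
        probs = {d: rating_probabilities for d in ALL_DOMAINS}
    else:
        probs = {d: rating_probabilities[d] for d in ALL_DOMAINS}
    for d, p in probs.items():
        if abs(sum(p) - 1.0) > 1e-9 or any(v < 0 for v in p):
            raise ConfigError(f"rating probabilities for {d} must be a simplex point")
    rng = substream(seed, "quadas")
    ids = study_ids or [f"study_{i + 1:03d}" for i in range(n_studies)]
    out = []
    for sid in ids:
        ratings = {
            d: ["low", "unclear", "high"][rng.choice(3, p=probs[d])] for d in ALL_DOMAINS
        }
        out.append(QuadasAssessment(study_id=sid, ratings=ratings))
    return out


# ---------------------------------------------------------------------------
# Default scenario


def default_meta_scenario(seed: int) -> list[MetaSimConfig]:
    """Study-level scenario echoing a four-marker NSCLC serum panel.

    Study counts and pooled accuracies mirror the scale of published
    NSCLC serum-marker meta-analyses: a CEA-like marker (many studies, low
    sensitivity, stage-dependent specificity), a Cyfra 21-1-like marker
    (most studies, high specificity), an HE4-like marker (balanced and
    stage-invariant) and an SAA-like marker (few studies, accurate, strong
    threshold effect).  Between-study correlations follow the threshold
    orientation.
    """
    return [
        MetaSimConfig(
            biomarker="CEA",
            n_studies=31,
            true_sens=0.51,
            true_spec=0.90,
            tau2_sens=0.3,
            tau2_spec=0.3,
            rho=-0.55,
            covariate_effects={"late_majority": ("spec", -0.8)},
            seed=seed,
        ),
        MetaSimConfig(
            biomarker="CYFRA211",
            n_studies=44,
            true_sens=0.62,
            true_spec=0.90,
            tau2_sens=0.3,
            tau2_spec=0.3,
            rho=-0.36,
            covariate_effects={"late_majority": ("spec", -0.8)},
            seed=seed,
        ),
        MetaSimConfig(
            biomarker="HE4",
            n_studies=24,
            true_sens=0.73,
            true_spec=0.83,
            tau2_sens=0.3,
            tau2_spec=0.3,
            rho=-0.47,
            seed=seed,
        ),
        MetaSimConfig(
            biomarker="SAA",
            n_studies=6,
            true_sens=0.73,
            true_spec=0.85,
            tau2_sens=0.3,
            tau2_spec=0.3,
            rho=-0.77,
            seed=seed,
        ),
    ]


def default_cohort_scenario(seed: int) -> CohortSimConfig:
    """70 matched pairs (35 healthy + 35 benign controls), four markers.

    Target AUCs follow the ordering SAA > HE4 > Cyfra 21-1 > CEA; all
    markers carry a LUSC/LLCC-over-LUAD histology effect and an over-65 age
    effect, and all but the HE4-like marker a late-stage effect.
    """
    common_hist = {"LUSC": 0.5, "LLCC": 0.5, "LUAD": -0.3}
    return CohortSimConfig(
        n_pairs=70,
        biomarkers=[
            BiomarkerSimSpec(
                name="CEA",
                control_log_mean=math.log(2.0),
                target_auc=0.77,
                stage_effect=0.5,
                histology_effects=common_hist,
                age_effect=0.4,
            ),
            BiomarkerSimSpec(
                name="CYFRA211",
                control_log_mean=math.log(1.8),
                target_auc=0.83,
                stage_effect=0.5,
                histology_effects=common_hist,
                age_effect=0.4,
            ),
            BiomarkerSimSpec(
                name="HE4",
                control_log_mean=math.log(45.0),
                log_sd=0.6,
                target_auc=0.84,
                stage_effect=0.0,
                histology_effects=common_hist,
                age_effect=0.4,
            ),
            BiomarkerSimSpec(
                name="SAA",
                control_log_mean=math.log(4.0),
                target_auc=0.88,
                stage_effect=0.5,
                histology_effects=common_hist,
                age_effect=0.4,
            ),
        ],
        healthy_fraction=0.5,
        pct_late=0.4,
        seed=seed,
    )


def default_quadas_probs() -> dict[str, tuple[float, float, float]]:
    """Domain-wise rating mix: elevated bias risk in patient selection and
    index test (the case-control design signature), cleaner elsewhere."""
    return {
        "risk_patient_selection": (0.35, 0.25, 0.40),
        "risk_index_test": (0.40, 0.25, 0.35),
        "risk_reference_standard": (0.75, 0.15, 0.10),
        "risk_flow_timing": (0.70, 0.20, 0.10),
        "appl_patient_selection": (0.90, 0.10, 0.0),
        "appl_index_test": (0.90, 0.10, 0.0),
        "appl_reference_standard": (0.90, 0.10, 0.0),
    }
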