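"""Patient-level ROC statistics: AUC oracle, Hanley–McNeil SE, paired tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from serodta.validation import (
    KIT_CUTOFFS,
    PatientRecord,
    cohort_frame,
    cohort_to_2x2,
    combine_biomarkers,
    compare_auc_independent,
    dichotomize_by_cutoff,
    empirical_auc,
    hanley_mcneil_se,
    paired_group_test,
    read_cohort_csv,
    stratified_auc,
    validate_cohort,
    write_cohort_csv,
)


def enumeration_auc(cases, controls):
    """Exhaustive pair count: concordant + half ties over all case×control pairs."""
    total = 0.0
    for c in cases:
        for k in controls:
            total += 1.0 if c > k else (0.5 if c == k else 0.0)
    return total / (len(cases) * len(controls))


class TestEmpiricalAUC:
    def test_small_worked_example(self):
        est = empirical_auc([3, 5, 7, 1, 2, 6], ["case"] * 3 + ["control"] * 3)
        assert est.auc == pytest.approx(7 / 9)

    def test_perfect_separation(self):
        est = empirical_auc([10, 11, 1, 2], ["case", "case", "control", "control"])
        assert est.auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            empirical_auc([1, 2], ["case", "case"])

    @given(
        cases=st.lists(st.integers(0, 20), min_size=1, max_size=25),
        controls=st.lists(st.integers(0, 20), min_size=1, max_size=25),
    )
    def test_equals_exhaustive_enumeration(self, cases, controls):
        values = cases + controls
        labels = ["case"] * len(cases) + ["control"] * len(controls)
        est = empirical_auc(values, labels)
        assert est.auc == pytest.approx(enumeration_auc(cases, controls), abs=1e-12)

    @given(
        cases=st.lists(st.floats(0.1, 50.0), min_size=2, max_size=20),
        controls=st.lists(st.floats(0.1, 50.0), min_size=2, max_size=20),
    )
    def test_invariant_under_monotone_transform(self, cases, controls):
        values = np.array(cases + controls)
        labels = ["case"] * len(cases) + ["control"] * len(controls)
        a = empirical_auc(values, labels).auc
        b = empirical_auc(np.log(values), labels).auc
        c = empirical_auc(values**3, labels).auc
        assert a == pytest.approx(b, abs=1e-12)
        assert a == pytest.approx(c, abs=1e-12)

    def test_hanley_mcneil_se_matches_hand_formula(self):
        # direct evaluation of the Q1/Q2 formula at A=0.8, n=50/50
        a, n1, n0 = 0.8, 50, 50
        q1 = a / (2 - a)
        q2 = 2 * a * a / (1 + a)
        var = (a * (1 - a) + 49 * (q1 - a * a) + 49 * (q2 - a * a)) / 2500
        assert hanley_mcneil_se(a, n1, n0) == pytest.approx(math.sqrt(var), abs=1e-12)
        assert hanley_mcneil_se(a, n1, n0) == pytest.approx(0.044502, abs=1e-6)


class TestCompareIndependentAUC:
    def test_identical_estimates(self):
        est = empirical_auc([3, 5, 7, 1, 2, 6], ["case"] * 3 + ["control"] * 3)
        z, p = compare_auc_independent(est, est)
        assert z == 0.0
        assert p == 1.0

    def test_zero_combined_se_rejected(self):
        a = empirical_auc([10, 11, 1, 2], ["case", "case", "control", "control"])
        with pytest.raises(ValueError):
            compare_auc_independent(a, a)

    def test_distinct_performance_detected(self, rng):
        strong = empirical_auc(
            np.concatenate([rng.normal(2.5, 1, 70), rng.normal(0, 1, 70)]),
            ["case"] * 70 + ["control"] * 70,
        )
        weak = empirical_auc(
            np.concatenate([rng.normal(0.3, 1, 70), rng.normal(0, 1, 70)]),
            ["case"] * 70 + ["control"] * 70,
        )
        _, p = compare_auc_independent(strong, weak)
        assert p < 0.05


class TestCombineBiomarkers:
    def _frame(self, rng, n=60, informative=(1.0, 1.0)):
        labels = ["case"] * n + ["control"] * n
        cols = {}
        for j, shift in enumerate(informative):
            vals = np.exp(
                np.concatenate([rng.normal(shift, 1, n), rng.normal(0, 1, n)])
            )
            cols[f"M{j}"] = vals
        return pd.DataFrame(cols), labels

    def test_single_marker_combination_equals_marker_auc(self, rng):
        frame, labels = self._frame(rng, informative=(1.0,))
        combo = combine_biomarkers(frame, labels, ["M0"])
        direct = empirical_auc(frame["M0"], labels)
        assert combo.auc.auc == pytest.approx(direct.auc, abs=1e-12)

    def test_two_informative_markers_do_not_hurt(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            frame, labels = self._frame(rng, informative=(0.8, 0.8))
            combo = combine_biomarkers(frame, labels, ["M0", "M1"])
            best_single = max(
                empirical_auc(frame[c], labels).auc for c in frame.columns
            )
            wins += combo.auc.auc >= best_single - 0.01
        assert wins >= 17  # ≥95% nominal, 20 replicates

    def test_permuted_labels_give_chance_auc(self, rng):
        frame, labels = self._frame(rng, informative=(1.0, 0.8))
        permuted = list(rng.permutation(labels))
        combo = combine_biomarkers(frame, permuted, ["M0", "M1"])
        assert abs(combo.auc.auc - 0.5) < 3 * combo.auc.se

    def test_perfect_separation_falls_back_to_ridge(self):
        frame = pd.DataFrame({"M0": [10.0, 11.0, 12.0, 1.0, 1.1, 1.2]})
        labels = ["case"] * 3 + ["control"] * 3
        combo = combine_biomarkers(frame, labels, ["M0"])
        assert combo.ridge_fallback
        assert combo.auc.auc == 1.0


class TestPairedGroupTest:
    def test_identical_vectors(self):
        stat, p, info = paired_group_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0
        assert "zero" in info["note"]

    def test_constant_shift_detected(self):
        x = np.arange(1.0, 13.0)
        _, p, info = paired_group_test(x + 2.0, x)
        assert p < 0.01
        assert info["t_p"] < 0.01

    def test_matches_exact_sign_rank_enumeration(self, rng):
        """Brute force over all 2^n sign assignments of |d| ranks."""
        for trial in range(5):
            d = rng.normal(0.4, 1.0, 10)
            d = np.where(d == 0, 0.17, d)  # no zeros, continuous → no ties
            x = rng.normal(5, 1, 10)
            stat, p, _ = paired_group_test(x + d, x)
            ranks = np.argsort(np.argsort(np.abs(d))) + 1
            w_obs = ranks[d > 0].sum()
            n = len(d)
            count = 0
            for signs in itertools.product([0, 1], repeat=n):
                w = sum(r for r, s in zip(ranks, signs) if s)
                # two-sided: as or more extreme than observed W+
                if min(w, n * (n + 1) / 2 - w) <= min(w_obs, n * (n + 1) / 2 - w_obs):
                    count += 1
            assert p == pytest.approx(count / 2**n, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_group_test([1.0], [1.0, 2.0])


class TestDichotomization:
    def make_patient(self, value, group="case", **kw):
        kw.setdefault("stage", "early" if group == "case" else "none")
        kw.setdefault("histology", "LUAD" if group == "case" else "none")
        kw.setdefault("control_type", "none" if group == "case" else "healthy")
        return PatientRecord(
            subject_id=kw.pop("subject_id", "x"), group=group, pair_id=kw.pop("pair_id", "p1"),
            biomarker_values={"HE4": value}, age=60, sex="F", **kw,
        )

    @pytest.mark.parametrize(
        "value, cutoff, expected",
        [(80.0, 70.0, True), (9.9, 10.0, False), (70.0, 70.0, True)],
    )
    def test_cutoff_rule(self, value, cutoff, expected):
        assert dichotomize_by_cutoff(self.make_patient(value), "HE4", cutoff) is expected

    def test_missing_value_raises(self):
        with pytest.raises(KeyError):
            dichotomize_by_cutoff(self.make_patient(80.0), "SAA", 10.0)

    def test_aggregation_totals(self, rng):
        records = []
        for i in range(30):
            records.append(
                self.make_patient(
                    float(rng.lognormal(4.5, 0.5)), group="case",
                    subject_id=f"c{i}", pair_id=f"p{i}",
                )
            )
            records.append(
                self.make_patient(
                    float(rng.lognormal(3.8, 0.5)), group="control",
                    subject_id=f"k{i}", pair_id=f"p{i}",
                )
            )
        rec, excluded = cohort_to_2x2(records, "HE4")
        assert not excluded
        assert rec.tp + rec.fn == 30
        assert rec.tn + rec.fp == 30
        assert rec.biomarker == "HE4"
        assert rec.extra_covariates["source"] == "experiment"

    def test_missing_subject_excluded_with_log(self):
        records = [
            self.make_patient(90.0, subject_id="c0", pair_id="p0"),
            self.make_patient(40.0, group="control", subject_id="k0", pair_id="p0"),
            PatientRecord(subject_id="c1", group="case", pair_id="p1",
                          biomarker_values={}, age=55, sex="M",
                          stage="late", histology="LUSC"),
        ]
        rec, excluded = cohort_to_2x2(records, "HE4")
        assert rec.tp + rec.fn == 1
        assert len(excluded) == 1 and "c1" in excluded[0]


def test_stratified_auc_detects_planted_subtype_effect():
    from serodta.synthetic import default_cohort_scenario, simulate_patient_cohort

    cfg = default_cohort_scenario(seed=5)
    cfg.n_pairs = 300  # large cohort so the planted LUSC > LUAD ordering is visible
    cohort = simulate_patient_cohort(cfg)
    strata = stratified_auc(cohort, "CEA", "histology")
    assert strata["LUSC"].auc > strata["LUAD"].auc
    age = stratified_auc(cohort, "CEA", "age")
    assert age["age_gt_65"].auc > age["age_le_65"].auc


def test_cohort_csv_round_trip(tmp_path):
    from serodta.synthetic import default_cohort_scenario, simulate_patient_cohort

    cohort = simulate_patient_cohort(default_cohort_scenario(seed=2))
    path = tmp_path / "cohort.csv"
    write_cohort_csv(cohort, path)
    assert read_cohort_csv(path) == cohort


def test_duplicate_pair_rejected():
    base = dict(biomarker_values={"HE4": 50.0}, age=60, sex="F",
                stage="none", histology="none", control_type="healthy")
    records = [
        PatientRecord(subject_id="a", group="control", pair_id="p1", **base),
        PatientRecord(subject_id="b", group="control", pair_id="p1", **base),
    ]
    with pytest.raises(ValueError, match="twice"):
        validate_cohort(records)
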