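import math
import statistics

import pytest

from cepsb.records import (
    AlternativeDiagnosis,
    CepsbError,
    CodeSystem,
    MedicalRecordAbstract,
    classify_gold,
    parse_code,
)
from cepsb.coding import ANAEMIA_DX, COMPLICATION_DX, EP_MAIN_DX, ErrorType
from cepsb.engine import apply, builtin_pragmatic, builtin_predefined
from cepsb.synthetic import (
    CohortConfig,
    ErrorInjectionModel,
    calibrate_default_model,
    generate_cohort,
    ideal_coding,
    inject_errors,
    DEFAULT_ERROR_TALLIES,
)

from oracles import case_type_probabilities


def icd(v):
    return parse_code(v, CodeSystem.ICD10)


def ccam(v):
    return parse_code(v, CodeSystem.CCAM)


class TestCohortConfig:
    def test_defaults_match_calibration_targets(self):
        cfg = CohortConfig()
        assert cfg.n_total == 370
        assert cfg.n_cases == 52
        assert cfg.n_stays_per_center == {"A": 230, "B": 140}
        assert cfg.cepsb_per_center == {"A": 28, "B": 24}
        assert (cfg.age_mean, cfg.age_sd) == (32.0, 6.6)
        assert (cfg.duration_mean, cfg.duration_sd) == (2.21, 1.7)

    def test_infeasible_case_count_rejected(self):
        with pytest.raises(CepsbError):
            CohortConfig(
                n_stays_per_center={"A": 10}, cepsb_per_center={"A": 11}
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(CepsbError):
            CohortConfig(n_stays_per_center={"A": -1})

    def test_dict_round_trip(self):
        cfg = CohortConfig(seed=99)
        assert CohortConfig.from_dict(cfg.to_dict()) == cfg


class TestIdealCoding:
    def _case(self, hemo=800.0, rupture=False, bleeding=False):
        return MedicalRecordAbstract(
            pregnancy_test_positive=True,
            ep_confirmed_histology=True,
            laparoscopy_performed=True,
            tubal_rupture=rupture,
            hemoperitoneum_cc=hemo,
            active_bleeding=bleeding,
        )

    def test_case_with_large_hemoperitoneum(self):
        hdd = ideal_coding(self._case(hemo=800.0))
        assert hdd.main_diagnosis == icd("O001")
        assert icd("K661") in hdd.associated_diagnoses
        assert ccam("JJFC001") in hdd.procedures

    def test_complication_codes_track_gold(self):
        hdd = ideal_coding(self._case(hemo=100.0, rupture=True, bleeding=True))
        assert icd("O086") in hdd.associated_diagnoses
        assert icd("O081") in hdd.associated_diagnoses
        assert icd("K661") not in hdd.associated_diagnoses

    def test_site_selects_main_diagnosis(self):
        assert ideal_coding(self._case(), site="ovarian").main_diagnosis == icd("O002")
        with pytest.raises(CepsbError):
            ideal_coding(self._case(), site="uterine")

    def test_uncomplicated_surgical_ep(self):
        gold = MedicalRecordAbstract(
            pregnancy_test_positive=True,
            ep_confirmed_histology=True,
            laparoscopy_performed=True,
            hemoperitoneum_cc=100.0,
            alternative_diagnosis=AlternativeDiagnosis.UNCOMPLICATED_EP,
        )
        hdd = ideal_coding(gold)
        assert hdd.main_diagnosis == icd("O001")
        assert ccam("JJFC001") in hdd.procedures
        assert not hdd.associated_diagnoses & COMPLICATION_DX

    def test_cyst_rupture_carries_no_ep_code(self):
        gold = MedicalRecordAbstract(
            laparoscopy_performed=True,
            alternative_diagnosis=AlternativeDiagnosis.OVARIAN_CYST_RUPTURE,
        )
        hdd = ideal_coding(gold)
        assert hdd.main_diagnosis not in EP_MAIN_DX
        assert not {c for c in hdd.all_diagnoses() if c.value.startswith("O00")}


class TestGenerateCohort:
    def test_default_counts_exact(self, default_cohort):
        assert len(default_cohort) == 370
        cases = [s for s in default_cohort if classify_gold(s.gold)]
        assert len(cases) == 52
        by_center = {
            c: sum(1 for s in cases if s.admin.center == c) for c in ("A", "B")
        }
        assert by_center == {"A": 28, "B": 24}

    def test_zero_case_config(self):
        cfg = CohortConfig(cepsb_per_center={"A": 0, "B": 0}, seed=5)
        cohort = generate_cohort(cfg)
        assert sum(classify_gold(s.gold) for s in cohort) == 0

    def test_determinism(self):
        cfg = CohortConfig(seed=123)
        assert generate_cohort(cfg) == generate_cohort(cfg)

    def test_seed_changes_output(self):
        assert generate_cohort(CohortConfig(seed=1)) != generate_cohort(
            CohortConfig(seed=2)
        )

    def test_exact_case_count_per_center_across_seeds(self):
        for seed in range(5):
            cohort = generate_cohort(CohortConfig(seed=seed))
            cases = [s for s in cohort if classify_gold(s.gold)]
            assert sum(1 for s in cases if s.admin.center == "A") == 28
            assert sum(1 for s in cases if s.admin.center == "B") == 24

    def test_ages_within_truncation_bounds(self, default_cohort):
        ages = [s.admin.age for s in default_cohort]
        assert min(ages) >= 18 and max(ages) <= 45
        assert 30.0 < statistics.mean(ages) < 34.0

    def test_durations_nonnegative_and_calibrated(self, default_cohort):
        durations = [s.admin.duration for s in default_cohort]
        assert min(durations) >= 0.0
        assert 1.7 < statistics.mean(durations) < 2.8

    def test_hemoperitoneum_at_least_500_for_that_subtype(self, default_cohort):
        for stay in default_cohort:
            if classify_gold(stay.gold) and icd("K661") in stay.hdd.associated_diagnoses:
                assert stay.gold.hemoperitoneum_cc >= 500.0

    def test_unique_stay_ids(self, default_cohort):
        ids = [s.stay_id for s in default_cohort]
        assert len(set(ids)) == len(ids)


class TestErrorFreeValidity:
    def test_guideline_algorithm_perfect_on_ideal_coding(self, default_cohort):
        preds = apply(builtin_predefined(), default_cohort).predictions
        for stay in default_cohort:
            assert preds[stay.stay_id] == classify_gold(stay.gold)

    def test_practice_algorithm_perfectly_sensitive_on_tubal_sites(self):
        # any missed error-free case must be a rare non-tubal site whose
        # main diagnosis is outside the practice code set
        cohort = generate_cohort(CohortConfig(seed=11))
        preds = apply(builtin_pragmatic(), cohort).predictions
        for stay in cohort:
            if classify_gold(stay.gold) and not preds[stay.stay_id]:
                assert stay.hdd.main_diagnosis in (icd("O000"), icd("O002"))


class TestErrorInjectionModel:
    def test_probability_bounds_enforced(self):
        with pytest.raises(CepsbError):
            ErrorInjectionModel(p_uncoded_stay=1.5)
        with pytest.raises(CepsbError):
            ErrorInjectionModel(p_excess_dx=-0.1)
        with pytest.raises(CepsbError):
            ErrorInjectionModel(max_errors_per_stay=0)

    def test_dict_round_trip(self):
        model = calibrate_default_model()
        assert ErrorInjectionModel.from_dict(model.to_dict()) == model


class TestCalibration:
    def test_absent_associated_probability(self):
        model = calibrate_default_model()
        assert model.p_absent_associated_dx == pytest.approx(19 / 52)

    def test_excess_probability(self):
        model = calibrate_default_model()
        assert model.p_excess_dx == pytest.approx(3 / 318)

    def test_all_probabilities_valid(self):
        model = calibrate_default_model()
        for error_type in ErrorType:
            assert 0.0 <= model.probability(error_type) <= 1.0

    def test_tallies_sum_to_49(self):
        assert sum(DEFAULT_ERROR_TALLIES.values()) == 49


class TestInjectErrors:
    def test_null_model_leaves_cohort_unchanged(self, default_cohort):
        mutated, log = inject_errors(default_cohort, ErrorInjectionModel(), seed=1)
        assert mutated == list(default_cohort)
        assert len(log) == 0

    def test_saturated_uncoded(self, default_cohort):
        model = ErrorInjectionModel(p_uncoded_stay=1.0)
        mutated, log = inject_errors(default_cohort, model, seed=1)
        for stay in mutated:
            if classify_gold(stay.gold):
                assert stay.hdd.is_uncoded
            else:
                assert not stay.hdd.is_uncoded  # excess-only stratum untouched
        assert len(log) == 52

    def test_reproducible(self, default_cohort, calibrated_model):
        first = inject_errors(default_cohort, calibrated_model, seed=42)
        second = inject_errors(default_cohort, calibrated_model, seed=42)
        assert first == second

    def test_max_errors_per_stay_respected(self, default_cohort, calibrated_model):
        _, log = inject_errors(default_cohort, calibrated_model, seed=4)
        for types in log.by_stay().values():
            assert len(types) <= calibrated_model.max_errors_per_stay

    def test_input_cohort_not_mutated(self, default_cohort, calibrated_model):
        snapshot = list(default_cohort)
        inject_errors(default_cohort, calibrated_model, seed=3)
        assert list(default_cohort) == snapshot

    def test_procedure_substitution_uses_nonspecific_sibling(self, default_cohort):
        model = ErrorInjectionModel(p_absent_ep_procedure=1.0)
        mutated, _ = inject_errors(default_cohort, model, seed=1)
        for stay in mutated:
            if classify_gold(stay.gold):
                assert ccam("JJFC006") in stay.hdd.procedures
                assert ccam("JJFC001") not in stay.hdd.procedures

    def test_excess_makes_noncase_fully_coded(self, default_cohort):
        model = ErrorInjectionModel(p_excess_dx=1.0)
        mutated, log = inject_errors(default_cohort, model, seed=1)
        preds = apply(builtin_predefined(), mutated).predictions
        for stay in mutated:
            if not classify_gold(stay.gold):
                assert preds[stay.stay_id]
        assert len(log) == 318

    def test_injected_counts_match_exact_expectation(
        self, default_cohort, calibrated_model
    ):
        """Empirical mean per-type counts over 200 replicates agree with
        the exact branch-enumeration expectation within 3 SD of the mean."""
        replicates = 200
        totals = {t: 0 for t in ErrorType}
        for r in range(replicates):
            _, log = inject_errors(default_cohort, calibrated_model, seed=5000 + r)
            for error_type, count in log.type_counts().items():
                totals[error_type] += count
        marginals = case_type_probabilities(calibrated_model)
        n_cases, n_controls = 52, 318
        for error_type in ErrorType:
            if error_type is ErrorType.EXCESS_DX:
                q, n = calibrated_model.p_excess_dx, n_controls
            else:
                q, n = marginals[error_type], n_cases
            expected = n * q
            sd_mean = math.sqrt(n * q * (1.0 - q) / replicates)
            observed = totals[error_type] / replicates
            assert abs(observed - expected) <= 3.0 * sd_mean + 1e-9, (
                error_type, observed, expected, sd_mean)


class TestSensitivityMonotonicity:
    @staticmethod
    def _mean_metric(algorithm, model, metric, replicates=40):
        values = []
        for r in range(replicates):
            cohort = generate_cohort(CohortConfig(seed=300 + r))
            mutated, _ = inject_errors(cohort, model, seed=600 + r)
            preds = apply(algorithm, mutated).predictions
            tp = fn = fp = tn = 0
            for stay in mutated:
                is_case = classify_gold(stay.gold)
                flagged = preds[stay.stay_id]
                tp += is_case and flagged
                fn += is_case and not flagged
                fp += flagged and not is_case
                tn += not flagged and not is_case
            values.append(tp / (tp + fn) if metric == "se" else tn / (tn + fp))
        return statistics.mean(values)

    def test_sensitivity_decreases_with_complication_deletion(self):
        base = self._mean_metric(builtin_predefined(), ErrorInjectionModel(), "se")
        hit = self._mean_metric(
            builtin_predefined(),
            ErrorInjectionModel(p_absent_complication_code=0.6),
            "se",
        )
        assert base == 1.0
        assert hit < base - 0.3

    def test_sensitivity_decreases_with_procedure_loss(self):
        base = self._mean_metric(builtin_pragmatic(), ErrorInjectionModel(), "se")
        hit = self._mean_metric(
            builtin_pragmatic(), ErrorInjectionModel(p_absent_ep_procedure=0.6), "se"
        )
        assert hit < base - 0.3

    def test_specificity_decreases_with_excess(self):
        base = self._mean_metric(builtin_predefined(), ErrorInjectionModel(), "sp")
        hit = self._mean_metric(
            builtin_predefined(), ErrorInjectionModel(p_excess_dx=0.2), "sp"
        )
        assert base == 1.0
        assert hit < base - 0.1

    def test_neutral_error_type_does_not_increase_sensitivity(self):
        base = self._mean_metric(builtin_predefined(), ErrorInjectionModel(), "se")
        hit = self._mean_metric(
            builtin_predefined(),
            ErrorInjectionModel(p_absent_associated_dx=0.8),
            "se",
        )
        assert hit <= base + 1e-9
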