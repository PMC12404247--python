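"""Reference-norms tests: predicted V̇O2 equations, table self-consistency,
percent transforms, the pressure–flow slope and the eligibility classifier."""

import json
import math

import numpy as np
import pytest

from oxpathway import (
    PhysiologyError,
    SubjectDemographics,
    control_eligibility,
    default_reference_table,
    mpap_co_slope,
    normal_parameter_values,
    percent_of_control,
    percent_predicted,
    predict_vo2,
    predicted_vo2_wasserman,
    validate_reference_models,
)
from oxpathway.norms import EligibilityCriteria, ReferenceModelTable
from oxpathway.estimation import PARAM_ORDER, PathwayParameters

from dataclasses import replace

from conftest import record_from_params


def _demo(sex="male", age=40.0, weight=80.0, height=178.0, group="control"):
    return SubjectDemographics(
        subject_id="X", age=age, sex=sex, height=height, weight=weight, group=group
    )


class TestWasserman:
    def test_male_example(self):
        assert predicted_vo2_wasserman(_demo()) == pytest.approx(2867.2, abs=0.1)

    def test_female_example(self):
        d = _demo(sex="female", age=50.0, weight=57.0, height=165.0)
        assert predicted_vo2_wasserman(d) == pytest.approx(1428.0, abs=0.1)

    def test_decreasing_in_age(self):
        preds = [predicted_vo2_wasserman(_demo(age=a)) for a in (20.0, 40.0, 60.0, 80.0)]
        assert all(b < a for a, b in zip(preds, preds[1:]))

    def test_age_range_warning(self):
        with pytest.warns(UserWarning):
            predicted_vo2_wasserman(_demo(age=105.0))

    def test_ideal_weight_branching_raises_underweight_prediction(self):
        thin = _demo(weight=50.0, height=185.0)
        assert predicted_vo2_wasserman(thin, ideal_weight_branching=True) > predicted_vo2_wasserman(thin)


class TestReferenceTable:
    def test_default_self_consistent_across_range(self, table):
        """Forward model on the normal values returns the predicted VO2
        (the calibration is exactly homogeneous; 5% is the stated bound)."""
        for v in (1000.0, 2000.0, 3000.0, 4000.0):
            normals, flags = normal_parameter_values(v, table)
            assert not flags
            assert predict_vo2(normals).vo2 == pytest.approx(v, rel=0.05)

    def test_constant_hb_model(self, table):
        n1, _ = normal_parameter_values(1500.0, table)
        n2, _ = normal_parameter_values(3500.0, table)
        assert n1.hb == n2.hb

    def test_floors_flagged(self, table):
        normals, flags = normal_parameter_values(1.0, table)
        assert flags  # tiny predicted VO2 floors the extensive parameters
        assert all(getattr(normals, p) > 0 for p in PARAM_ORDER)

    def test_negative_slope_rejected(self, table):
        models = dict(table.models)
        models["dm"] = (10.0, -0.001)
        with pytest.raises(PhysiologyError):
            ReferenceModelTable(models=models)

    def test_json_round_trip(self, table, tmp_path):
        path = tmp_path / "table.json"
        table.to_json(path)
        loaded = ReferenceModelTable.from_json(path)
        assert loaded.models == table.models
        assert loaded.provenance == table.provenance


class TestPercentTransforms:
    def test_percent_predicted(self, table):
        normals, _ = normal_parameter_values(2000.0, table)
        pct = percent_predicted(normals, normals)
        assert list(pct.keys()) == list(PARAM_ORDER)  # fixed output order
        assert all(v == pytest.approx(100.0) for v in pct.values())
        halved = replace(normals, dm=0.5 * normals.dm)
        assert percent_predicted(halved, normals)["dm"] == pytest.approx(50.0)

    def test_percent_of_control_worked_examples(self):
        pct, flags = percent_of_control({"dm": 35.5, "q": 12.6}, {"dm": 49.8, "q": 19.3})
        assert pct["dm"] == pytest.approx(71.3, abs=0.1)
        assert pct["q"] == pytest.approx(65.3, abs=0.1)
        assert not flags

    def test_percent_of_control_zero_control_flagged(self):
        pct, flags = percent_of_control({"x": 5.0}, {"x": 0.0})
        assert math.isnan(pct["x"]) and flags

    def test_scale_equivariance(self, table):
        normals, _ = normal_parameter_values(2000.0, table)
        doubled = PathwayParameters(**{p: 2 * getattr(normals, p) for p in PARAM_ORDER})
        assert percent_predicted(doubled, doubled) == percent_predicted(normals, normals)


class TestMpapCoSlope:
    def test_flat(self):
        assert mpap_co_slope(15.0, 6.0, 15.0, 19.2) == 0.0

    def test_control_median_example(self):
        assert mpap_co_slope(15.0, 6.0, 23.0, 19.2) == pytest.approx(0.606, abs=0.01)

    def test_threshold_exceeded(self):
        assert mpap_co_slope(15.0, 5.0, 45.0, 10.0) == pytest.approx(6.0)

    def test_requires_flow_rise(self):
        with pytest.raises(PhysiologyError):
            mpap_co_slope(15.0, 6.0, 23.0, 6.0)


@pytest.fixture(scope="module")
def control_record(table):
    normals, _ = normal_parameter_values(predicted_vo2_wasserman(_demo()), table)
    rec = record_from_params(normals)
    return replace(rec, rest_mpap=15.0, rest_co=6.0, mpap=23.0)


class TestEligibility:
    def test_healthy_control_passes(self, control_record):
        res = control_eligibility(control_record, _demo())
        assert res.eligible and not res.reasons

    def test_low_rer_fails_with_reason(self, control_record):
        res = control_eligibility(replace(control_record, rer=1.02), _demo())
        assert not res.eligible
        assert any("RER" in r for r in res.reasons)

    def test_high_rest_mpap_fails(self, control_record):
        res = control_eligibility(replace(control_record, rest_mpap=26.0), _demo())
        assert not res.eligible

    def test_missing_pressures_indeterminate_but_core_evaluable(self, control_record):
        rec = replace(control_record, rest_mpap=None, rest_co=None, mpap=None)
        res = control_eligibility(rec, _demo())
        assert res.checks["rest_mpap"] is None
        assert res.checks["mpap_co_slope"] is None
        assert res.checks["vo2_pct"] is not None
        assert res.eligible  # all evaluable criteria pass

    def test_monotone_improvement_never_flips_pass_to_fail(self, control_record):
        base = control_eligibility(control_record, _demo())
        better = control_eligibility(replace(control_record, rer=control_record.rer + 0.1), _demo())
        assert base.eligible and better.eligible


class TestValidateReferenceModels:
    def test_cohort_generated_from_table_recovers_coefficients(self, table):
        preds = [1200.0, 1800.0, 2400.0, 3000.0, 3600.0]
        estimates = [normal_parameter_values(v, table)[0] for v in preds]
        fitted, report = validate_reference_models(preds, estimates, table)
        for name in PARAM_ORDER:
            ti, ts = table.models[name]
            fi, fs = fitted.models[name]
            assert fs == pytest.approx(ts, abs=1e-9 + 1e-6 * abs(ts))
            assert fi == pytest.approx(ti, abs=1e-6 * max(1.0, abs(ti)))
            assert abs(report[name].get("rel_deviation", 0.0)) < 1e-6
        assert set(report) == set(PARAM_ORDER)  # always lists all six

    def test_too_few_subjects_rejected(self, table):
        est = [normal_parameter_values(2000.0, table)[0]] * 2
        with pytest.raises(PhysiologyError):
            validate_reference_models([2000.0, 2100.0], est)

    def test_degenerate_design_rejected(self, table):
        est = [normal_parameter_values(2000.0, table)[0]] * 3
        with pytest.raises(PhysiologyError):
            validate_reference_models([2000.0, 2000.0, 2000.0], est)


def test_eligibility_thresholds_validated():
    with pytest.raises(PhysiologyError):
        EligibilityCriteria(vo2_pct_min=-5.0)
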