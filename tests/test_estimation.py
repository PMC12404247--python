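"""Inverse-stage tests: Bohr integration against an independent fine-step
oracle, diffusion-capacity round trips through the forward model, and the
closure arithmetic for Vmax."""

import math
from dataclasses import replace

import numpy as np
import pytest

from oxpathway import (
    BloodPoint,
    InfeasibleOperatingPoint,
    PhysiologyError,
    bohr_integrate,
    default_reference_table,
    estimate_all,
    estimate_dl,
    estimate_dm,
    estimate_vmax,
    hb_saturation,
    normal_parameter_values,
    predict_vo2,
)
from oxpathway.estimation import (
    FLAG_DEGENERATE_DL,
    FLAG_UNRESOLVABLE_DL,
    PARAM_ORDER,
    EstimationSettings,
    PathwayParameters,
    bohr_end_po2,
)

from conftest import record_from_params


def _euler_end_po2(d, q, hb, driving, entry, n=200_000, hufner=1.34, sol=0.003):
    """Independent fine-step forward-Euler oracle for the capillary ODE in
    PO2 space (pure Python, no shared code path with the implementation)."""
    h = 1.0 / n
    p = entry
    for _ in range(n):
        x = p
        u = x * x * x + 150.0 * x
        ds = 23400.0 * (3.0 * x * x + 150.0) / (u + 23400.0) ** 2
        dcdp = hufner * hb * ds + sol
        p += h * d * (driving - p) / (10.0 * q * dcdp)
    return p


class TestBohrIntegration:
    def test_zero_diffusion_is_identity(self):
        entry = BloodPoint.from_po2(26.0, 14.9)
        out = bohr_integrate(0.0, 15.0, 14.9, 110.0, entry, "uptake")
        assert out == entry

    def test_bracket_max_equilibrates(self):
        entry = BloodPoint.from_po2(26.0, 14.9)
        out = bohr_integrate(5000.0, 15.0, 14.9, 110.0, entry, "uptake")
        assert abs(out.po2 - 110.0) < 0.5

    def test_end_po2_strictly_between_entry_and_driving(self):
        entry = BloodPoint.from_po2(26.0, 14.9)
        out = bohr_integrate(20.0, 15.0, 14.9, 110.0, entry, "uptake")
        assert 26.0 < out.po2 < 110.0
        rel = bohr_integrate(30.0, 15.0, 14.9, 1.0, BloodPoint.from_po2(100.0, 14.9), "release")
        assert 1.0 < rel.po2 < 100.0

    def test_direction_preconditions(self):
        entry = BloodPoint.from_po2(50.0, 14.9)
        with pytest.raises(PhysiologyError):
            bohr_integrate(20.0, 15.0, 14.9, 40.0, entry, "uptake")
        with pytest.raises(PhysiologyError):
            bohr_integrate(20.0, 15.0, 14.9, 60.0, entry, "release")
        with pytest.raises(PhysiologyError):
            bohr_integrate(-1.0, 15.0, 14.9, 60.0, entry, "uptake")

    def test_grid_refinement(self):
        """Halving the step count moves end content by < 1e-4 mL/dL."""
        hb = 14.9
        for n in (100,):
            e1 = bohr_end_po2(40.0, 15.0, hb, 110.0, 26.0, EstimationSettings(n_integration_steps=n))
            e2 = bohr_end_po2(40.0, 15.0, hb, 110.0, 26.0, EstimationSettings(n_integration_steps=2 * n))
            c1 = BloodPoint.from_po2(e1, hb).content
            c2 = BloodPoint.from_po2(e2, hb).content
            assert abs(c1 - c2) < 1e-4

    @pytest.mark.parametrize(
        "d, q, driving, entry",
        [(40.0, 15.0, 110.0, 26.0), (12.0, 8.0, 1.0, 95.0), (120.0, 25.0, 130.0, 30.0)],
    )
    def test_against_independent_euler_oracle(self, d, q, driving, entry):
        impl = bohr_end_po2(d, q, 14.9, driving, entry)
        oracle = _euler_end_po2(d, q, 14.9, driving, entry)
        assert impl == pytest.approx(oracle, abs=5e-3)


@pytest.fixture(scope="module")
def synthetic_record():
    """Self-consistent record with known DL = 21.5 and DM = 35.5.

    Vmax is iterated to the estimation closure (operating mitochondrial PO2
    equal to the assumed peak value) so the diffusion round trips are exact
    rather than carrying the closure's few-percent driving-pressure bias."""
    normals, _ = normal_parameter_values(2000.0, default_reference_table())
    truth = replace(normals, dl=21.5, dm=35.5)
    for _ in range(30):
        vo2 = predict_vo2(truth).vo2
        new_vmax = 1.3 * vo2
        if abs(new_vmax - truth.vmax) < 1e-8:
            break
        truth = replace(truth, vmax=new_vmax)
    return record_from_params(truth), truth


class TestDiffusionEstimates:
    def test_dl_round_trip(self, synthetic_record):
        rec, truth = synthetic_record
        assert estimate_dl(rec) == pytest.approx(truth.dl, rel=0.01)

    def test_dm_round_trip(self, synthetic_record):
        rec, truth = synthetic_record
        assert estimate_dm(rec) == pytest.approx(truth.dm, rel=0.01)

    def test_dl_monotone_in_arterial_target(self, synthetic_record):
        rec, _ = synthetic_record
        higher = replace(rec, arterial=BloodPoint.from_po2(rec.arterial.po2 + 3.0, rec.hb))
        assert estimate_dl(higher) > estimate_dl(rec)

    def test_dm_monotone_in_venous_target(self, synthetic_record):
        rec, _ = synthetic_record
        lower = replace(rec, venous=BloodPoint.from_po2(rec.venous.po2 - 2.0, rec.hb))
        assert estimate_dm(lower) > estimate_dm(rec)

    def test_unresolvable_arterial_above_alveolar(self, synthetic_record):
        from oxpathway.estimation import EstimationDiagnostics

        rec, _ = synthetic_record
        bad = replace(rec, arterial=BloodPoint.from_po2(200.0, rec.hb))
        diag = EstimationDiagnostics()
        d = estimate_dl(bad, diagnostics=diag)
        assert d == EstimationSettings().d_bracket[1]
        assert FLAG_UNRESOLVABLE_DL in diag.flags

    def test_degenerate_no_gradient(self, synthetic_record):
        from oxpathway.estimation import EstimationDiagnostics

        rec, _ = synthetic_record
        flat = replace(rec, arterial=BloodPoint.from_po2(rec.venous.po2, rec.hb))
        diag = EstimationDiagnostics()
        assert estimate_dl(flat, diagnostics=diag) == 0.0
        assert FLAG_DEGENERATE_DL in diag.flags
        assert estimate_dm(flat) == 0.0

    def test_venous_below_pmito_infeasible(self, synthetic_record):
        rec, _ = synthetic_record
        bad = replace(rec, venous=BloodPoint.from_po2(0.5, rec.hb))
        with pytest.raises(InfeasibleOperatingPoint, match="[Pp]mito"):
            estimate_dm(bad)


class TestVmaxClosure:
    def test_arithmetic(self):
        assert estimate_vmax(1000.0) == pytest.approx(1300.0)
        assert estimate_vmax(2835.0) == pytest.approx(3685.5, abs=0.5)

    def test_limit_small_p50(self):
        s = EstimationSettings(p50_mito=1e-9)
        assert estimate_vmax(1000.0, s) == pytest.approx(1000.0, rel=1e-6)

    def test_exceeds_vo2(self):
        assert estimate_vmax(1500.0) > 1500.0

    def test_positive_required(self):
        with pytest.raises(PhysiologyError):
            estimate_vmax(0.0)


class TestEstimateAll:
    def test_va_arithmetic(self, synthetic_record):
        rec, _ = synthetic_record
        rec2 = replace(rec, ve=47.14, vd_vt=0.30)
        params, _ = estimate_all(rec2)
        assert params.va == pytest.approx(33.0, abs=0.01)

    def test_va_fallback_without_vdvt(self, synthetic_record):
        from oxpathway.estimation import FLAG_VA_FALLBACK

        rec, _ = synthetic_record
        rec2 = replace(rec, vd_vt=None, vco2=2000.0, paco2=40.0)
        params, diag = estimate_all(rec2)
        assert params.va == pytest.approx(863.0 * 2.0 / 40.0)
        assert FLAG_VA_FALLBACK in diag.flags

    def test_deterministic(self, synthetic_record):
        rec, _ = synthetic_record
        p1, _ = estimate_all(rec)
        p2, _ = estimate_all(rec)
        assert p1.as_tuple() == p2.as_tuple()

    def test_zero_noise_cohort_recovery(self, zero_noise_cohort):
        """Noise-free records: VA, DL, Q, Hb, DM recover to < 1% median
        error; Vmax carries the fixed-Pmito closure scatter, bounded a
        priori by |(1 + P50m)·VO2/Vmax_true − 1| with worst-case lognormal
        spread, i.e. < 10% median (see the methods note)."""
        errs = {p: [] for p in PARAM_ORDER}
        for demo, rec, truth, _ in zero_noise_cohort:
            params, _ = estimate_all(rec)
            for p in PARAM_ORDER:
                errs[p].append(abs(getattr(params, p) - getattr(truth, p)) / getattr(truth, p))
        for p in ("va", "dl", "q", "hb", "dm"):
            assert np.median(errs[p]) < 0.01, p
        assert np.median(errs["vmax"]) < 0.10
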