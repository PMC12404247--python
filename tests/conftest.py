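"""Shared fixtures: reference table, self-consistent synthetic records and a
small zero-noise cohort (session-scoped; generation is deterministic)."""

from __future__ import annotations

import pytest

from oxpathway import (
    BloodPoint,
    GeneratorConfig,
    NoiseModel,
    PeakMeasurementRecord,
    default_reference_table,
    generate_cohort,
    predict_vo2,
)
from oxpathway.estimation import PathwayParameters


@pytest.fixture(scope="session")
def table():
    return default_reference_table()


def record_from_params(params: PathwayParameters, subject_id: str = "SYN", vd_vt: float = 0.30) -> PeakMeasurementRecord:
    """Build a perfectly self-consistent measured record from the forward
    model's operating point at the given true parameters."""
    op = predict_vo2(params)
    return PeakMeasurementRecord(
        subject_id=subject_id,
        vo2=op.vo2,
        vco2=1.1 * op.vo2,
        ve=params.va / (1.0 - vd_vt),
        vd_vt=vd_vt,
        co=params.q,
        hb=params.hb,
        arterial=BloodPoint.from_po2(op.arterial.po2, params.hb),
        paco2=40.0,
        venous=BloodPoint.from_po2(op.venous.po2, params.hb),
        rer=1.1,
    )


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """24 subjects (8 per group), zero measurement noise, fixed seed."""
    cfg = GeneratorConfig(n_control=8, n_pasc=8, n_cfs=8, seed=42, noise=NoiseModel.none())
    subjects, failures = generate_cohort(cfg)
    assert failures == 0
    return subjects
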