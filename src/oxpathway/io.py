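"""Subject-CSV reading/writing.

The subject schema (one row per subject, UTF-8, "." decimal separator):
``subject_id, group, age, sex, height_cm, weight_kg, vo2_ml_min,
vco2_ml_min, ve_l_min, vd_vt, co_l_min, hb_g_dl, pao2_mmhg, paco2_mmhg,
sao2_pct, pvo2_mmhg, svo2_pct, rer`` plus optional ``mpap_mmhg, pcwp_mmhg,
rap_mmhg, hr_bpm, lactate_mmol_l, rest_mpap_mmhg, rest_co_l_min`` (left
empty when missing). Saturations are percent in files and fractions in
memory.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import List, Optional, Tuple, Union

import pandas as pd

from .core import (
    BloodPoint,
    CurveSettings,
    PeakMeasurementRecord,
    SubjectDemographics,
)

__all__ = ["REQUIRED_COLUMNS", "OPTIONAL_COLUMNS", "read_subjects", "subjects_from_frame"]

REQUIRED_COLUMNS = (
    "subject_id", "group", "age", "sex", "height_cm", "weight_kg",
    "vo2_ml_min", "vco2_ml_min", "ve_l_min", "vd_vt", "co_l_min", "hb_g_dl",
    "pao2_mmhg", "paco2_mmhg", "sao2_pct", "pvo2_mmhg", "svo2_pct", "rer",
)
OPTIONAL_COLUMNS = (
    "mpap_mmhg", "pcwp_mmhg", "rap_mmhg", "hr_bpm", "lactate_mmol_l",
    "rest_mpap_mmhg", "rest_co_l_min",
)


def _opt(row, col) -> Optional[float]:
    if col not in row or row[col] is None:
        return None
    v = row[col]
    try:
        v = float(v)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(v) else v


def subjects_from_frame(
    df: pd.DataFrame, curve: CurveSettings = CurveSettings()
) -> List[Tuple[SubjectDemographics, PeakMeasurementRecord]]:
    """Build typed (demographics, record) pairs from a schema DataFrame.

    Saturations are converted percent→fraction; blood points carry the
    measured PO2 with content computed under the active curve coefficients.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns and c != "vd_vt"]
    if missing:
        raise ValueError(f"subject table missing required columns: {missing}")
    out = []
    for _, row in df.iterrows():
        demo = SubjectDemographics(
            subject_id=str(row["subject_id"]),
            age=float(row["age"]),
            sex=str(row["sex"]),
            height=float(row["height_cm"]),
            weight=float(row["weight_kg"]),
            group=str(row["group"]),
        )
        hb = float(row["hb_g_dl"])
        arterial = BloodPoint.from_so2(
            float(row["sao2_pct"]) / 100.0, hb, curve, po2=float(row["pao2_mmhg"])
        )
        venous = BloodPoint.from_so2(
            float(row["svo2_pct"]) / 100.0, hb, curve, po2=float(row["pvo2_mmhg"])
        )
        rec = PeakMeasurementRecord(
            subject_id=demo.subject_id,
            vo2=float(row["vo2_ml_min"]),
            vco2=float(row["vco2_ml_min"]),
            ve=float(row["ve_l_min"]),
            vd_vt=_opt(row, "vd_vt"),
            co=float(row["co_l_min"]),
            hb=hb,
            arterial=arterial,
            paco2=float(row["paco2_mmhg"]),
            venous=venous,
            rer=float(row["rer"]),
            mpap=_opt(row, "mpap_mmhg"),
            pcwp=_opt(row, "pcwp_mmhg"),
            rap=_opt(row, "rap_mmhg"),
            hr=_opt(row, "hr_bpm"),
            lactate=_opt(row, "lactate_mmol_l"),
            rest_mpap=_opt(row, "rest_mpap_mmhg"),
            rest_co=_opt(row, "rest_co_l_min"),
        )
        out.append((demo, rec))
    return out


def read_subjects(
    path: Union[str, Path], curve: CurveSettings = CurveSettings()
) -> List[Tuple[SubjectDemographics, PeakMeasurementRecord]]:
    """Read a subject CSV into typed records."""
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise ValueError(f"no subjects in {path}")
    return subjects_from_frame(df, curve)
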