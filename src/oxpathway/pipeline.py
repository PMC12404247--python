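"""End-to-end cohort analysis: estimate → normals → VDR → group statistics.

This module glues the stages together in the order the method runs and
produces the figure-ready tables: per-subject parameter estimates, VDR
percentages, percent-predicted (heat-map) and percent-of-control (radar)
exports, summary tables and omnibus/post hoc statistics. Row-level failures
are recorded per subject and never abort the cohort run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import CurveSettings, Environment, PeakMeasurementRecord, PhysiologyError, SubjectDemographics, extraction_ratio
from .estimation import PARAM_ORDER, EstimationSettings, estimate_all
from .forward import predict_vo2, vdr, vdr_cohort_summary
from .norms import (
    EligibilityCriteria,
    ReferenceModelTable,
    control_eligibility,
    default_reference_table,
    normal_parameter_values,
    percent_of_control,
    percent_predicted,
    predicted_vo2_wasserman,
)
from .stats import kruskal_wallis, pairwise_posthoc, summary_table

__all__ = ["AnalysisResult", "analyze_cohort", "RADAR_VARIABLES"]

#: peak-exercise variables exported as percent-of-control (radar plot data)
RADAR_VARIABLES = ("vo2_ml_min", "co_l_min", "ser", "vd_vt", "rap_mmhg", "pcwp_mmhg")

#: variables summarized in the cohort table
SUMMARY_VARIABLES = (
    "vo2_ml_min", "co_l_min", "ser", "pao2_mmhg", "pvo2_mmhg",
    "sao2_pct", "svo2_pct", "vd_vt",
    "va_l_min", "dl_ml_min_mmhg", "q_l_min", "hb_g_dl", "dm_ml_min_mmhg", "vmax_ml_min",
)

_PARAM_COLUMNS = {
    "va": "va_l_min",
    "dl": "dl_ml_min_mmhg",
    "q": "q_l_min",
    "hb": "hb_g_dl",
    "dm": "dm_ml_min_mmhg",
    "vmax": "vmax_ml_min",
}


@dataclass
class AnalysisResult:
    parameters: pd.DataFrame  # per-subject estimates + diagnostics
    vdr: pd.DataFrame  # per-subject VDR percentages
    vdr_summary: Dict  # per-group medians with bootstrap CIs
    percent_predicted: pd.DataFrame  # heat-map export
    radar: pd.DataFrame  # percent-of-control export
    summary: pd.DataFrame  # Table-style medians/IQRs with p values
    tests: Dict  # per-variable omnibus + post hoc results
    eligibility: pd.DataFrame
    failures: Dict[str, str] = field(default_factory=dict)


def analyze_cohort(
    subjects: Sequence[Tuple[SubjectDemographics, PeakMeasurementRecord]],
    table: Optional[ReferenceModelTable] = None,
    env: Environment = Environment(),
    settings: EstimationSettings = EstimationSettings(),
    curve: CurveSettings = CurveSettings(),
    criteria: EligibilityCriteria = EligibilityCriteria(),
    seed: int = 0,
    posthoc_method: str = "rank_sum",
) -> AnalysisResult:
    """Run the full per-subject and group-level analysis."""
    table = table or default_reference_table()
    param_rows: List[dict] = []
    vdr_rows: List[dict] = []
    pct_rows: List[dict] = []
    elig_rows: List[dict] = []
    failures: Dict[str, str] = {}

    for demo, rec in subjects:
        base = {"subject_id": demo.subject_id, "group": demo.group}
        try:
            params, diag = estimate_all(rec, env, settings, curve)
        except (PhysiologyError, RuntimeError) as exc:
            failures[demo.subject_id] = f"estimation failed: {exc}"
            continue
        predicted = predicted_vo2_wasserman(demo)
        normals, norm_flags = normal_parameter_values(predicted, table)

        row = dict(base)
        for name in PARAM_ORDER:
            row[_PARAM_COLUMNS[name]] = getattr(params, name)
        row["pao2_alveolar_mmhg"] = diag.pao2
        row["flags"] = ";".join(list(diag.flags) + list(norm_flags))
        row["residual_mmhg"] = max(
            v for v in (diag.dl_residual, diag.dm_residual, 0.0) if not math.isnan(v)
        )
        row["predicted_vo2_ml_min"] = predicted
        param_rows.append(row)

        pct = percent_predicted(params, normals)
        pct_rows.append({**base, **{f"pct_{name}": pct[name] for name in PARAM_ORDER}})

        try:
            res = vdr(params, rec.vo2, predicted, normals, env, settings, curve)
            vdr_rows.append(
                {
                    **base,
                    **{f"vdr_{name}": res.vdr[name] for name in PARAM_ORDER},
                    "deficit_ml_min": res.deficit,
                    "applicable": res.applicable,
                }
            )
        except (PhysiologyError, RuntimeError) as exc:
            failures[demo.subject_id] = f"vdr failed: {exc}"

        elig = control_eligibility(rec, demo, criteria)
        elig_rows.append(
            {
                **base,
                "eligible": elig.eligible,
                **{f"check_{k}": v for k, v in elig.checks.items()},
                "reasons": ";".join(elig.reasons),
            }
        )

    params_df = pd.DataFrame(param_rows)
    vdr_df = pd.DataFrame(vdr_rows)
    pct_df = pd.DataFrame(pct_rows)
    elig_df = pd.DataFrame(elig_rows)

    # measured-variable table for summaries/radar
    meas_rows = []
    for demo, rec in subjects:
        meas_rows.append(
            {
                "subject_id": demo.subject_id,
                "group": demo.group,
                "vo2_ml_min": rec.vo2,
                "co_l_min": rec.co,
                "ser": extraction_ratio(rec.arterial.content, rec.venous.content),
                "vd_vt": rec.vd_vt if rec.vd_vt is not None else math.nan,
                "pao2_mmhg": rec.arterial.po2,
                "pvo2_mmhg": rec.venous.po2,
                "sao2_pct": 100.0 * rec.arterial.so2,
                "svo2_pct": 100.0 * rec.venous.so2,
                "rap_mmhg": rec.rap if rec.rap is not None else math.nan,
                "pcwp_mmhg": rec.pcwp if rec.pcwp is not None else math.nan,
            }
        )
    meas_df = pd.DataFrame(meas_rows)
    merged = meas_df.merge(
        params_df[["subject_id"] + list(_PARAM_COLUMNS.values())], on="subject_id", how="left"
    ) if not params_df.empty else meas_df

    # radar: per-group medians as percent of the control-group median
    radar_rows = []
    if "control" in set(meas_df["group"]):
        control_medians = meas_df[meas_df["group"] == "control"].median(numeric_only=True)
        for group in dict.fromkeys(meas_df["group"]):
            gm = meas_df[meas_df["group"] == group].median(numeric_only=True)
            pct, _ = percent_of_control(
                {v: gm.get(v, math.nan) for v in RADAR_VARIABLES},
                {v: control_medians.get(v, math.nan) for v in RADAR_VARIABLES},
            )
            for var, val in pct.items():
                radar_rows.append({"group": group, "variable": var, "pct_of_control": val})
    radar_df = pd.DataFrame(radar_rows)

    summary_df = summary_table(merged, SUMMARY_VARIABLES, method=posthoc_method)

    tests: Dict[str, Dict] = {}
    for var in SUMMARY_VARIABLES:
        if var not in merged.columns:
            continue
        groups = {
            g: merged.loc[merged["group"] == g, var].dropna().to_numpy()
            for g in dict.fromkeys(merged["group"])
        }
        groups = {g: v for g, v in groups.items() if v.size > 0}
        if len(groups) < 2:
            continue
        kw = kruskal_wallis(groups)
        ph = pairwise_posthoc(groups, method=posthoc_method)
        tests[var] = {
            "kruskal_wallis": {"h": kw.h, "df": kw.df, "p": kw.p, "p_exact": kw.p_exact},
            "posthoc": [
                {
                    "pair": list(r.pair), "p_raw": r.p_raw, "p_adjusted": r.p_adjusted,
                    "significant": r.significant, "letter": r.letter, "testable": r.testable,
                }
                for r in ph
            ],
        }

    vdr_values: Dict[str, Dict[str, list]] = {}
    if not vdr_df.empty:
        for group in dict.fromkeys(vdr_df["group"]):
            sub = vdr_df[(vdr_df["group"] == group) & vdr_df["applicable"]]
            vdr_values[group] = {
                name: sub[f"vdr_{name}"].tolist() for name in PARAM_ORDER
            }
    vdr_summary = vdr_cohort_summary(vdr_values, seed=seed)

    return AnalysisResult(
        parameters=params_df,
        vdr=vdr_df,
        vdr_summary=vdr_summary,
        percent_predicted=pct_df,
        radar=radar_df,
        summary=summary_df,
        tests=tests,
        eligibility=elig_df,
        failures=failures,
    )
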