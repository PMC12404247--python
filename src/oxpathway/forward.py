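"""Forward stage: achievable V̇O2 from a parameter set, and the VDR analysis.

:func:`predict_vo2` solves the coupled O2 transport/utilization system for a
given six-parameter set — the operating point simultaneously satisfying

(i)   alveolar mass balance       PAO2 = PIO2 − 863·(V̇O2/1000)/V̇a
(ii)  lung Bohr integration       venous → arterial against PAO2 with D_L
(iii) Fick principle              V̇O2 = 10·Q̇·(CaO2 − CvO2)
(iv)  muscle Bohr integration     arterial → venous against Pmito with D_M
(v)   mitochondrial demand        V̇O2 = Vmax·Pmito/(Pmito + P50mito)

The solver scans V̇O2 ∈ (0, Vmax): for a candidate V̇O2, (v) fixes Pmito and
(i) fixes PAO2; a damped fixed-point iteration on the venous PO2 then closes
the lung–muscle loop (ii)+(iv), and the mismatch between the circulatory
transport (iii) and the candidate V̇O2 is driven to zero by bracketing root
finding. Transport supply decreases and demand back-pressure increases with
V̇O2, so the root is unique; the procedure is fully deterministic.

:func:`vdr` is the counterfactual V̇O2-deficit-recovery analysis: each
sub-normal parameter is raised to its predicted-normal value (one at a time,
others held at the subject's estimates), the forward model is re-solved, and
the V̇O2 gain is expressed as a percent of the subject's deficit
(Wasserman-predicted minus measured V̇O2peak).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np
from scipy.optimize import brentq

from .core import (
    BloodPoint,
    CurveSettings,
    Environment,
    InfeasibleOperatingPoint,
    PhysiologyError,
)
from .estimation import (
    PARAM_ORDER,
    EstimationSettings,
    PathwayParameters,
    _bohr_end_po2_k,
    _content_k,
    njit,
)

__all__ = [
    "OperatingPoint",
    "VdrResult",
    "predict_vo2",
    "vdr",
    "vdr_cohort_summary",
]

#: fixed-point damping / iteration budget for the venous-PO2 inner loop
_DAMPING = 0.5
_MAX_INNER = 500
_INNER_TOL = 1e-8  # mmHg on venous PO2
#: convergence threshold on the largest relative residual of (i)-(v)
_RESIDUAL_TOL = 1e-3


@dataclass(frozen=True)
class OperatingPoint:
    """A self-consistent solution of the forward transport model."""

    vo2: float  # mL/min
    pao2: float  # mmHg
    arterial: BloodPoint
    venous: BloodPoint
    pmito: float  # mmHg
    converged: bool
    residuals: Dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class VdrResult:
    """Per-subject V̇O2 deficit recovery.

    ``vdr[x]`` is 100·(V̇O2 after normalizing x − measured)/(deficit); zero
    for parameters at or above normal, NaN where the counterfactual solve
    failed (see ``notes``). ``applicable`` is False when the subject has no
    deficit (measured ≥ predicted), in which case all VDR are undefined.
    """

    vdr: Dict[str, float]
    recovered_vo2: Dict[str, float]
    deficit: float  # mL/min, predicted − measured
    predicted_vo2: float
    measured_vo2: float
    applicable: bool
    notes: Dict[str, str] = field(default_factory=dict)


@njit(cache=True)
def _transport_mismatch_k(
    vo2: float,
    va: float,
    dl: float,
    q: float,
    hb: float,
    vmax: float,
    pio2: float,
    pmito: float,
    dm: float,
    n: int,
    hufner: float,
    sol: float,
    scale: float,
    damping: float,
    max_inner: int,
    inner_tol: float,
    pv_init: float,
) -> tuple:
    """Inner closure of (ii)+(iv) at a candidate VO2; returns
    (10Q(Ca−Cv) − VO2, arterial PO2, venous PO2, inner converged).

    The venous PO2 fixed point of the composite lung→muscle map is solved by
    a secant iteration on g(pv) = M(L(pv)) − pv (the map is a contraction,
    so g is monotone near the root) with a damped-iteration fallback step
    whenever the secant update leaves the feasible (Pmito, PAO2) range.
    ``pv_init`` warm-starts the iteration across outer VO2 evaluations."""
    pao2 = pio2 - 0.863 * vo2 / va
    pv0 = pv_init
    if not (pmito < pv0 < pao2):
        pv0 = pmito + 0.5 * (pao2 - pmito)
        if pv0 > 40.0:
            pv0 = 40.0

    def _g(pv):
        pa = _bohr_end_po2_k(dl, q, hb, pao2, pv, n, hufner, sol, scale)
        return _bohr_end_po2_k(dm, q, hb, pmito, pa, n, hufner, sol, scale) - pv

    g0 = _g(pv0)
    pv1 = pv0 + g0  # one plain fixed-point step seeds the secant
    ok = False
    if abs(g0) < inner_tol:
        pv1 = pv0
        ok = True
    else:
        g1 = _g(pv1)
        for _ in range(max_inner):
            if abs(g1) < inner_tol:
                ok = True
                break
            denom = g1 - g0
            if denom == 0.0:
                pv_next = pv1 + g1
            else:
                pv_next = pv1 - g1 * (pv1 - pv0) / denom
            if not (pmito < pv_next < pao2):
                pv_next = pv1 + damping * g1  # damped fallback inside range
            pv0, g0 = pv1, g1
            pv1 = pv_next
            g1 = _g(pv1)
    pv = pv1
    pa = _bohr_end_po2_k(dl, q, hb, pao2, pv, n, hufner, sol, scale)
    ca = _content_k(pa, hb, hufner, sol, scale)
    cv = _content_k(pv, hb, hufner, sol, scale)
    return 10.0 * q * (ca - cv) - vo2, pa, pv, ok


def predict_vo2(
    params: PathwayParameters,
    env: Environment = Environment(),
    settings: EstimationSettings = EstimationSettings(),
    curve: CurveSettings = CurveSettings(),
) -> OperatingPoint:
    """Solve the forward O2-pathway model for the achievable V̇O2peak."""
    for name in PARAM_ORDER:
        v = getattr(params, name)
        if not math.isfinite(v) or v <= 0:
            raise PhysiologyError(f"parameter {name} must be finite and positive, got {v!r}")
    pio2 = env.pio2
    p50m = settings.p50_mito
    n = settings.n_integration_steps
    args = (curve.hufner, curve.solubility, curve.p50_scale, _DAMPING, _MAX_INNER, _INNER_TOL)
    warm = [-1.0]  # venous PO2 warm start carried across outer evaluations

    def mismatch(vo2: float) -> float:
        pmito = p50m * vo2 / (params.vmax - vo2)
        g, _, pv, _ = _transport_mismatch_k(
            vo2, params.va, params.dl, params.q, params.hb, params.vmax,
            pio2, pmito, params.dm, n, *args, warm[0],
        )
        warm[0] = pv
        return g

    # VO2 is bounded by the mitochondrial asymptote and by ventilation
    # (PAO2 must stay positive, kept >= 1 mmHg here).
    vent_cap = params.va * (pio2 - 1.0) / 0.863
    if vent_cap <= 0:
        raise InfeasibleOperatingPoint("inspired PO2 too low for any positive VO2")
    hi = min(params.vmax * (1.0 - 1e-9), vent_cap)
    lo = min(1e-6 * params.vmax, 1e-3)
    g_lo = mismatch(lo)
    if g_lo <= 0:
        raise InfeasibleOperatingPoint(
            "transport cannot supply even a vanishing VO2 with these parameters"
        )
    g_hi = mismatch(hi)
    if g_hi >= 0:
        raise InfeasibleOperatingPoint(
            "ventilation-limited: supply still exceeds demand at the feasible VO2 cap "
            f"(cap {hi:.1f} mL/min)"
        )
    vo2 = brentq(mismatch, lo, hi, xtol=1e-4, rtol=8.9e-16, maxiter=300)

    pmito = p50m * vo2 / (params.vmax - vo2)
    g, pa, pv, inner_ok = _transport_mismatch_k(
        vo2, params.va, params.dl, params.q, params.hb, params.vmax,
        pio2, pmito, params.dm, n, *args, warm[0],
    )
    pao2 = pio2 - 0.863 * vo2 / params.va
    arterial = BloodPoint.from_po2(pa, params.hb, curve)
    venous = BloodPoint.from_po2(pv, params.hb, curve)
    demand = params.vmax * pmito / (pmito + p50m)
    residuals = {
        "fick_vs_vo2": abs(g) / vo2,
        "mito_demand": abs(demand - vo2) / vo2,
        "lung_vs_muscle": 0.0 if inner_ok else math.inf,
    }
    converged = inner_ok and max(residuals.values()) < _RESIDUAL_TOL
    if not converged:
        raise InfeasibleOperatingPoint(
            f"forward solve did not converge: residuals {residuals}"
        )
    return OperatingPoint(
        vo2=vo2, pao2=pao2, arterial=arterial, venous=venous, pmito=pmito,
        converged=converged, residuals=residuals,
    )


def vdr(
    estimated: PathwayParameters,
    measured_vo2: float,
    predicted_vo2: float,
    normals: PathwayParameters,
    env: Environment = Environment(),
    settings: EstimationSettings = EstimationSettings(),
    curve: CurveSettings = CurveSettings(),
) -> VdrResult:
    """Sequential single-parameter normalization (V̇O2 deficit recovery).

    Normalization is one-sided: only sub-normal parameters are raised (a
    supra-normal value is left alone and scores 0). The denominator is the
    deficit against the Wasserman-predicted V̇O2. Raw values are reported —
    a single normalization may overshoot the deficit and exceed 100%.
    """
    if predicted_vo2 <= 0:
        raise PhysiologyError("predicted VO2 must be positive")
    deficit = predicted_vo2 - measured_vo2
    if deficit <= 0:
        return VdrResult(
            vdr={name: math.nan for name in PARAM_ORDER},
            recovered_vo2={name: math.nan for name in PARAM_ORDER},
            deficit=deficit, predicted_vo2=predicted_vo2, measured_vo2=measured_vo2,
            applicable=False,
            notes={"deficit": "measured VO2 at or above predicted; VDR undefined"},
        )
    out: Dict[str, float] = {}
    rec_vo2: Dict[str, float] = {}
    notes: Dict[str, str] = {}
    for name in PARAM_ORDER:
        est_x = getattr(estimated, name)
        norm_x = getattr(normals, name)
        if not est_x < norm_x:
            out[name] = 0.0
            rec_vo2[name] = measured_vo2
            continue
        counterfactual = replace(estimated, **{name: norm_x})
        try:
            op = predict_vo2(counterfactual, env, settings, curve)
        except (PhysiologyError, RuntimeError) as exc:  # per-parameter isolation
            out[name] = math.nan
            rec_vo2[name] = math.nan
            notes[name] = f"counterfactual solve failed: {exc}"
            continue
        out[name] = 100.0 * (op.vo2 - measured_vo2) / deficit
        rec_vo2[name] = op.vo2
        if out[name] > 100.0:
            notes[name] = "normalization overshoots the deficit (>100%)"
    return VdrResult(
        vdr=out, recovered_vo2=rec_vo2, deficit=deficit,
        predicted_vo2=predicted_vo2, measured_vo2=measured_vo2,
        applicable=True, notes=notes,
    )


def vdr_cohort_summary(
    vdr_values: Dict[str, Dict[str, list]],
    seed: int = 0,
    n_boot: int = 2000,
) -> Dict[str, Dict[str, Dict[str, float]]]:
    """Cohort-level VDR medians with percentile-bootstrap 95% CIs.

    ``vdr_values[group][param]`` is the list of per-subject VDR percentages
    (NaNs from non-applicable subjects are dropped). Bootstrap is seeded and
    uses 2000 resamples by default.
    """
    rng = np.random.default_rng(seed)
    out: Dict[str, Dict[str, Dict[str, float]]] = {}
    for group, per_param in vdr_values.items():
        out[group] = {}
        for param, values in per_param.items():
            arr = np.asarray([v for v in values if not math.isnan(v)], dtype=float)
            if arr.size == 0:
                out[group][param] = {"median": math.nan, "ci_lo": math.nan, "ci_hi": math.nan, "n": 0}
                continue
            idx = rng.integers(0, arr.size, size=(n_boot, arr.size))
            boots = np.median(arr[idx], axis=1)
            out[group][param] = {
                "median": float(np.median(arr)),
                "ci_lo": float(np.percentile(boots, 2.5)),
                "ci_hi": float(np.percentile(boots, 97.5)),
                "n": int(arr.size),
            }
    return out
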