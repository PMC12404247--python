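"""Inverse stage: per-subject estimation of the six O2-pathway parameters.

The six parameters of the transport/utilization cascade are

* V̇a   alveolar ventilation (L/min) — dead-space-corrected ventilation,
* D_L   lung O2 diffusion capacity (mL/min/mmHg),
* Q̇    cardiac output (L/min) — taken as the measured direct-Fick value,
* Hb    hemoglobin (g/dL) — measured,
* D_M   skeletal-muscle O2 diffusion capacity (mL/min/mmHg),
* Vmax  mitochondrial oxidative-phosphorylation capacity (mL/min).

D_L and D_M are recovered by Bohr integration of blood O2 content along the
pulmonary and muscle capillaries: the capillary is traversed in normalized
transit time τ ∈ [0, 1] under Fick's law of diffusion against a fixed driving
pressure (alveolar PO2 in the lung, mitochondrial PO2 in the muscle),

    dC/dτ = D · (P_driving − P(C)) / (10 · Q̇),

with the nonlinear dissociation curve linking content and pressure. The
integration is performed in PO2 space via the chain rule (identical
trajectory, no curve inversion needed), fixed-step classical 4th-order
Runge–Kutta. D is then the unique value for which the end-capillary pressure
matches the measured arterial (lung) or venous (muscle) point, found by
bisection on log10 D.

Vmax uses the mitochondrial Michaelis–Menten closure at an assumed peak
mitochondrial PO2 (``Pmito_peak``): VO2 = Vmax · Pmito/(Pmito + P50mito), so
Vmax = VO2peak · (Pmito_peak + P50mito)/Pmito_peak. The Pmito assumption is
flagged in diagnostics of every estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

from .core import (
    BloodPoint,
    CurveSettings,
    Environment,
    InfeasibleOperatingPoint,
    PeakMeasurementRecord,
    PhysiologyError,
    ALVEOLAR_GAS_CONSTANT,
    alveolar_po2,
    alveolar_ventilation,
)

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit
except ImportError:  # pragma: no cover - numba is a declared dependency

    def njit(*args, **kwargs):  # type: ignore[misc]
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco


__all__ = [
    "PathwayParameters",
    "EstimationSettings",
    "EstimationDiagnostics",
    "PARAM_ORDER",
    "bohr_integrate",
    "bohr_end_po2",
    "estimate_dl",
    "estimate_dm",
    "estimate_vmax",
    "estimate_all",
    "effective_alveolar_ventilation",
]

#: Canonical ordering of the six pathway parameters in all vector outputs.
PARAM_ORDER = ("va", "dl", "q", "hb", "dm", "vmax")

FLAG_UNRESOLVABLE_DL = "unresolvable: arterial exceeds alveolar"
FLAG_DEGENERATE_DL = "degenerate: no arteriovenous gradient across lung"
FLAG_DEGENERATE_DM = "degenerate: no extraction across muscle"
FLAG_PMITO_ASSUMPTION = "Vmax closure: Pmito_peak assumed"
FLAG_VA_FALLBACK = "VA from 863*VCO2/PaCO2 fallback (Vd/Vt missing)"


@dataclass(frozen=True)
class PathwayParameters:
    """The six-parameter O2 pathway tuple (native units, see module docs)."""

    va: float
    dl: float
    q: float
    hb: float
    dm: float
    vmax: float

    def __post_init__(self) -> None:
        for name in PARAM_ORDER:
            v = getattr(self, name)
            if math.isfinite(v) and v <= 0:
                raise PhysiologyError(f"pathway parameter {name} must be positive, got {v!r}")

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in PARAM_ORDER}

    def as_tuple(self) -> Tuple[float, ...]:
        return tuple(getattr(self, name) for name in PARAM_ORDER)


@dataclass(frozen=True)
class EstimationSettings:
    """Numerical settings shared by the inverse and forward stages.

    ``pmito_peak`` and ``p50_mito`` are the mitochondrial closure assumptions
    (mmHg); they are not measurable from iCPET and are exposed here precisely
    because every Vmax (and D_M driving pressure) is conditional on them.
    """

    pmito_peak: float = 1.0  # assumed mitochondrial PO2 at peak exercise, mmHg
    p50_mito: float = 0.3  # mitochondrial Michaelis constant, mmHg
    n_integration_steps: int = 200
    end_po2_tol: float = 1e-4  # mmHg, bisection stopping tolerance
    d_bracket: Tuple[float, float] = (0.05, 5000.0)  # mL/min/mmHg

    def __post_init__(self) -> None:
        if self.pmito_peak <= 0 or self.p50_mito <= 0:
            raise PhysiologyError("mitochondrial pressures must be positive")
        if self.n_integration_steps < 10:
            raise PhysiologyError("need at least 10 integration steps")
        if not 0 < self.d_bracket[0] < self.d_bracket[1]:
            raise PhysiologyError("invalid diffusion search bracket")


@dataclass
class EstimationDiagnostics:
    """Per-subject diagnostics accompanying a parameter estimate."""

    pao2: float = math.nan  # computed alveolar PO2, mmHg
    dl_residual: float = math.nan  # |end-capillary − measured arterial| PO2, mmHg
    dm_residual: float = math.nan  # |end-capillary − measured venous| PO2, mmHg
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Integration kernels (numba)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _sat_k(p: float, scale: float) -> float:
    if p <= 0.0:
        return 0.0
    x = p / scale
    u = x * x * x + 150.0 * x
    return u / (u + 23400.0)


@njit(cache=True)
def _dcdp_k(p: float, hb: float, hufner: float, sol: float, scale: float) -> float:
    # d(content)/d(PO2): Hb-bound slope plus solubility; strictly positive.
    if p < 0.0:
        p = 0.0
    x = p / scale
    u = x * x * x + 150.0 * x
    du = (3.0 * x * x + 150.0) / scale
    ds = 23400.0 * du / ((u + 23400.0) * (u + 23400.0))
    return hufner * hb * ds + sol


@njit(cache=True)
def _content_k(p: float, hb: float, hufner: float, sol: float, scale: float) -> float:
    return hufner * hb * _sat_k(p, scale) + sol * p


@njit(cache=True)
def _bohr_end_po2_k(
    d: float,
    q: float,
    hb: float,
    driving: float,
    entry: float,
    n: int,
    hufner: float,
    sol: float,
    scale: float,
) -> float:
    # RK4 on dP/dτ = d·(driving − P)/(10·q·dCdP(P)); τ ∈ [0, 1], n fixed steps.
    # Explicit RK4 is unstable when the local rate constant
    # k = d/(10·q·dCdP) satisfies k·h >> 1 (near-equilibrated, flat-curve
    # region at large d); each fixed step is subdivided so k·h_sub ≲ 0.4,
    # bounding k by the *flattest* curve slope the step can reach — dCdP is
    # smallest toward the high-PO2 end of the [entry, driving] range, so the
    # rate is sampled at both the current P and the driving pressure.
    if d <= 0.0:
        return entry
    h = 1.0 / n
    tenq = 10.0 * q
    dcdp_drv = _dcdp_k(driving, hb, hufner, sol, scale)
    p = entry
    for _ in range(n):
        dcdp_min = _dcdp_k(p, hb, hufner, sol, scale)
        if dcdp_drv < dcdp_min:
            dcdp_min = dcdp_drv
        k_rate = d / (tenq * dcdp_min)
        m = 1
        kh = k_rate * h
        if kh > 0.8:
            m = int(kh / 0.4) + 1
            if m > 20000:
                m = 20000
        hs = h / m
        for _ in range(m):
            k1 = d * (driving - p) / (tenq * _dcdp_k(p, hb, hufner, sol, scale))
            p2 = p + 0.5 * hs * k1
            k2 = d * (driving - p2) / (tenq * _dcdp_k(p2, hb, hufner, sol, scale))
            p3 = p + 0.5 * hs * k2
            k3 = d * (driving - p3) / (tenq * _dcdp_k(p3, hb, hufner, sol, scale))
            p4 = p + hs * k3
            k4 = d * (driving - p4) / (tenq * _dcdp_k(p4, hb, hufner, sol, scale))
            p = p + hs * (k1 + 2.0 * k2 + 2.0 * k3 + k4) / 6.0
            if p < 0.0:
                p = 0.0
    return p


def bohr_end_po2(
    d: float,
    q: float,
    hb: float,
    driving_po2: float,
    entry_po2: float,
    settings: EstimationSettings = EstimationSettings(),
    curve: CurveSettings = CurveSettings(),
) -> float:
    """End-capillary PO2 of the Bohr integration (thin kernel wrapper)."""
    if d < 0:
        raise PhysiologyError("diffusion capacity must be non-negative")
    if q <= 0:
        raise PhysiologyError("blood flow must be positive")
    return _bohr_end_po2_k(
        float(d),
        float(q),
        float(hb),
        float(driving_po2),
        float(entry_po2),
        settings.n_integration_steps,
        curve.hufner,
        curve.solubility,
        curve.p50_scale,
    )


def bohr_integrate(
    d: float,
    q: float,
    hb: float,
    driving_po2: float,
    entry: BloodPoint,
    direction: str = "uptake",
    settings: EstimationSettings = EstimationSettings(),
    curve: CurveSettings = CurveSettings(),
) -> BloodPoint:
    """Integrate blood O2 content along one capillary transit.

    ``direction`` is ``"uptake"`` (lung: driving pressure above entry PO2) or
    ``"release"`` (muscle: driving below entry). Returns the end-capillary
    blood point; for 0 < D < ∞ the end PO2 lies strictly between the entry
    PO2 and the driving pressure.
    """
    if direction not in ("uptake", "release"):
        raise PhysiologyError(f"unknown direction {direction!r}")
    if direction == "uptake" and driving_po2 <= entry.po2:
        raise PhysiologyError("uptake requires driving PO2 above entry PO2")
    if direction == "release" and driving_po2 >= entry.po2:
        raise PhysiologyError("release requires driving PO2 below entry PO2")
    end_p = bohr_end_po2(d, q, hb, driving_po2, entry.po2, settings, curve)
    return BloodPoint.from_po2(end_p, hb, curve)


# ---------------------------------------------------------------------------
# Diffusion-capacity solvers
# ---------------------------------------------------------------------------


def _solve_d(
    target_po2: float,
    q: float,
    hb: float,
    driving_po2: float,
    entry_po2: float,
    settings: EstimationSettings,
    curve: CurveSettings,
) -> Tuple[float, float]:
    """Bisection on log10 D for end-capillary PO2 == target.

    The end PO2 is monotone in D (toward the driving pressure), so plain
    bisection on the log-scaled bracket is robust across the ~5 decades of
    the search range. Returns (D, |end − target|)."""
    lo, hi = settings.d_bracket
    llo, lhi = math.log10(lo), math.log10(hi)
    toward_driving = 1.0 if driving_po2 > entry_po2 else -1.0

    def end(d: float) -> float:
        return _bohr_end_po2_k(
            d, q, hb, driving_po2, entry_po2,
            settings.n_integration_steps, curve.hufner, curve.solubility, curve.p50_scale,
        )

    e_lo, e_hi = end(lo), end(hi)
    # target beyond what the bracket can reach -> clamp at the nearer endpoint
    if toward_driving * (target_po2 - e_hi) >= 0:
        return hi, abs(e_hi - target_po2)
    if toward_driving * (e_lo - target_po2) >= 0:
        return lo, abs(e_lo - target_po2)
    d_mid, e_mid = lo, e_lo
    for _ in range(100):
        lmid = 0.5 * (llo + lhi)
        d_mid = 10.0**lmid
        e_mid = end(d_mid)
        if abs(e_mid - target_po2) < settings.end_po2_tol:
            break
        if toward_driving * (e_mid - target_po2) < 0:
            llo = lmid
        else:
            lhi = lmid
    return d_mid, abs(e_mid - target_po2)


def effective_alveolar_ventilation(rec: PeakMeasurementRecord) -> Tuple[float, Optional[str]]:
    """V̇a from V̇e·(1−Vd/Vt) when Vd/Vt is present, else the
    863·V̇CO2/PaCO2 fallback that keeps partial records usable."""
    if rec.vd_vt is not None:
        return alveolar_ventilation(rec.ve, rec.vd_vt), None
    if rec.paco2 <= 0:
        raise PhysiologyError("PaCO2 needed for the VA fallback")
    va = ALVEOLAR_GAS_CONSTANT * (rec.vco2 / 1000.0) / rec.paco2
    return va, FLAG_VA_FALLBACK


def estimate_dl(
    rec: PeakMeasurementRecord,
    env: Environment = Environment(),
    settings: EstimationSettings = EstimationSettings(),
    curve: CurveSettings = CurveSettings(),
    diagnostics: Optional[EstimationDiagnostics] = None,
) -> float:
    """Lung O2 diffusion capacity: the unique D for which venous blood
    integrated against alveolar PO2 ends at the measured arterial PO2.

    End-capillary PO2 is equated to measured arterial PO2 (no shunt or V/Q
    heterogeneity terms). When the measured arterial PO2 exceeds the computed
    alveolar PO2 the estimate is unresolvable: D_L is reported at the bracket
    maximum with an ``unresolvable`` flag rather than aborting the subject.
    """
    diag = diagnostics if diagnostics is not None else EstimationDiagnostics()
    va, va_flag = effective_alveolar_ventilation(rec)
    if va_flag:
        diag.flags.append(va_flag)
    pao2 = alveolar_po2(rec.vo2, va, env)
    diag.pao2 = pao2
    if pao2 <= rec.arterial.po2:
        diag.flags.append(FLAG_UNRESOLVABLE_DL)
        diag.dl_residual = rec.arterial.po2 - pao2
        return settings.d_bracket[1]
    if rec.arterial.po2 <= rec.venous.po2 + settings.end_po2_tol:
        diag.flags.append(FLAG_DEGENERATE_DL)
        diag.dl_residual = 0.0
        return 0.0
    d, resid = _solve_d(rec.arterial.po2, rec.co, rec.hb, pao2, rec.venous.po2, settings, curve)
    diag.dl_residual = resid
    return d


def estimate_dm(
    rec: PeakMeasurementRecord,
    settings: EstimationSettings = EstimationSettings(),
    curve: CurveSettings = CurveSettings(),
    diagnostics: Optional[EstimationDiagnostics] = None,
) -> float:
    """Muscle O2 diffusion capacity: the unique D for which arterial blood
    released against the assumed mitochondrial PO2 ends at the measured
    venous point (targets matched on PO2; the venous blood point couples
    content and pressure one-to-one through the dissociation curve)."""
    diag = diagnostics if diagnostics is not None else EstimationDiagnostics()
    if rec.venous.po2 <= settings.pmito_peak:
        raise InfeasibleOperatingPoint(
            f"measured PvO2 {rec.venous.po2:g} mmHg does not exceed the assumed "
            f"peak mitochondrial PO2 {settings.pmito_peak:g} mmHg (Pmito closure)"
        )
    if rec.arterial.po2 <= rec.venous.po2 + settings.end_po2_tol:
        diag.flags.append(FLAG_DEGENERATE_DM)
        diag.dm_residual = 0.0
        return 0.0
    d, resid = _solve_d(
        rec.venous.po2, rec.co, rec.hb, settings.pmito_peak, rec.arterial.po2, settings, curve
    )
    diag.dm_residual = resid
    return d


def estimate_vmax(vo2peak: float, settings: EstimationSettings = EstimationSettings()) -> float:
    """Mitochondrial capacity from the Michaelis–Menten closure at the
    assumed peak mitochondrial PO2; always exceeds VO2peak."""
    if vo2peak <= 0:
        raise PhysiologyError("VO2peak must be positive")
    return vo2peak * (settings.pmito_peak + settings.p50_mito) / settings.pmito_peak


def estimate_all(
    rec: PeakMeasurementRecord,
    env: Environment = Environment(),
    settings: EstimationSettings = EstimationSettings(),
    curve: CurveSettings = CurveSettings(),
) -> Tuple[PathwayParameters, EstimationDiagnostics]:
    """Estimate the full six-parameter set for one subject.

    V̇a comes from the dead-space correction (or VCO2/PaCO2 fallback), Q̇ is
    the measured direct-Fick cardiac output, Hb is measured; D_L, D_M and
    Vmax via the solvers above. Deterministic for fixed inputs and settings.
    """
    diag = EstimationDiagnostics()
    va, va_flag = effective_alveolar_ventilation(rec)
    if va_flag:
        diag.flags.append(va_flag)
    dl = estimate_dl(rec, env, settings, curve, diagnostics=diag)
    # estimate_dl re-derives VA; drop its duplicate fallback flag if any
    if va_flag and diag.flags.count(va_flag) > 1:
        diag.flags.remove(va_flag)
    dm = estimate_dm(rec, settings, curve, diagnostics=diag)
    vmax = estimate_vmax(rec.vo2, settings)
    diag.flags.append(FLAG_PMITO_ASSUMPTION)
    params = PathwayParameters(va=va, dl=dl, q=rec.co, hb=rec.hb, dm=dm, vmax=vmax)
    return params, diag
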