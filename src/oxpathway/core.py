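"""Domain types, unit conventions and closed-form gas-exchange primitives.

Unit conventions are fixed package-wide:

* V̇O2 / V̇CO2 in mL/min (STPD), ventilation and blood flow in L/min,
* O2 contents in mL O2 per dL blood, pressures in mmHg,
* saturations stored as *fractions* internally; percent is accepted only at
  I/O boundaries.

The dL→L unit bridge (factor 10) appears only inside :func:`fick_vo2` /
:func:`fick_q`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

from scipy.optimize import brentq

__all__ = [
    "PhysiologyError",
    "InfeasibleOperatingPoint",
    "CurveSettings",
    "SEVERINGHAUS_P50",
    "ALVEOLAR_GAS_CONSTANT",
    "bohr_shifted_curve",
    "SubjectDemographics",
    "Environment",
    "BloodPoint",
    "PeakMeasurementRecord",
    "hb_saturation",
    "po2_from_saturation",
    "o2_content",
    "extraction_ratio",
    "alveolar_ventilation",
    "alveolar_po2",
    "fick_vo2",
    "fick_q",
    "body_surface_area",
]


class PhysiologyError(ValueError):
    """An input lies outside the physically meaningful domain of an operation."""


class InfeasibleOperatingPoint(PhysiologyError):
    """The requested operating point cannot be supported by the given parameters
    (e.g. ventilation too low to sustain the requested O2 uptake)."""


#: Conversion constant of the alveolar mass balance, mmHg · (L/min) / (L/min)
#: after the mL→L bridge on V̇O2; ties STPD gas uptake to BTPS ventilation.
ALVEOLAR_GAS_CONSTANT = 863.0

#: P50 of the standard (unshifted) Severinghaus dissociation curve — the root
#: of P^3 + 150 P = 23400.
SEVERINGHAUS_P50 = 26.8571


@dataclass(frozen=True)
class CurveSettings:
    """Oxyhemoglobin dissociation curve and O2-content coefficients.

    ``hufner``      mL O2 bound per g Hb at full saturation (1.34 by default,
                    common iCPET practice; 1.36/1.39 variants configurable).
    ``solubility``  physically dissolved O2, mL/dL per mmHg.
    ``p50``         effective half-saturation pressure; shifting it rescales
                    the Severinghaus curve along the PO2 axis (Bohr effect).
    """

    hufner: float = 1.34
    solubility: float = 0.003
    p50: float = SEVERINGHAUS_P50

    def __post_init__(self) -> None:
        if self.hufner <= 0 or self.solubility < 0 or self.p50 <= 0:
            raise PhysiologyError("curve coefficients must be positive")

    @property
    def p50_scale(self) -> float:
        """Multiplicative PO2 rescaling relative to the standard curve."""
        return self.p50 / SEVERINGHAUS_P50


def bohr_shifted_curve(
    paco2: float = 40.0,
    ph: Optional[float] = None,
    hco3: float = 24.0,
    base: CurveSettings = CurveSettings(),
) -> CurveSettings:
    """Optional Bohr-effect shift: P50 scaled by pH (measured or estimated
    from PaCO2 via Henderson–Hasselbalch at the given bicarbonate), using the
    standard Bohr coefficient d log10 P50 / d pH = −0.48.

    The default pipeline uses the unshifted curve; this helper implements the
    configurable shift model.
    """
    if ph is None:
        if paco2 <= 0 or hco3 <= 0:
            raise PhysiologyError("PaCO2 and HCO3 must be positive")
        ph = 6.1 + math.log10(hco3 / (0.03 * paco2))
    p50 = base.p50 * 10.0 ** (0.48 * (7.4 - ph))
    return replace(base, p50=p50)


_DEFAULT_CURVE = CurveSettings()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectDemographics:
    subject_id: str
    age: float  # years
    sex: str  # "female" | "male"
    height: float  # cm
    weight: float  # kg
    group: str  # "control" | "PASC" | "CFS"

    def __post_init__(self) -> None:
        if self.age <= 0 or self.height <= 0 or self.weight <= 0:
            raise PhysiologyError("age, height and weight must be positive")
        if self.sex not in ("female", "male"):
            raise PhysiologyError(f"unknown sex {self.sex!r}")


@dataclass(frozen=True)
class Environment:
    """Ambient conditions entering the alveolar O2 mass balance."""

    barometric_pressure: float = 760.0  # mmHg
    fio2: float = 0.21  # fraction
    water_vapor_pressure: float = 47.0  # mmHg at body temperature

    def __post_init__(self) -> None:
        if not 0.0 < self.fio2 <= 1.0:
            raise PhysiologyError("FiO2 must lie in (0, 1]")
        if self.barometric_pressure <= self.water_vapor_pressure:
            raise PhysiologyError("barometric pressure must exceed water vapor pressure")

    @property
    def pio2(self) -> float:
        """Inspired PO2, FiO2 · (Pb − PH2O), mmHg."""
        return self.fio2 * (self.barometric_pressure - self.water_vapor_pressure)


@dataclass(frozen=True)
class BloodPoint:
    """One blood O2 state: partial pressure, saturation and content.

    The three fields are mutually consistent under the active dissociation
    curve; use the constructors rather than assembling fields by hand.
    """

    po2: float  # mmHg
    so2: float  # fraction in [0, 1)
    content: float  # mL O2 / dL

    @classmethod
    def from_po2(cls, po2: float, hb: float, curve: CurveSettings = _DEFAULT_CURVE) -> "BloodPoint":
        s = hb_saturation(po2, curve)
        return cls(po2=po2, so2=s, content=o2_content(hb, s, po2, curve))

    @classmethod
    def from_so2(
        cls,
        so2: float,
        hb: float,
        curve: CurveSettings = _DEFAULT_CURVE,
        po2: Optional[float] = None,
    ) -> "BloodPoint":
        """Build from a measured saturation; PO2 taken as measured when given,
        otherwise inverted from the curve."""
        p = po2_from_saturation(so2, curve) if po2 is None else po2
        return cls(po2=p, so2=so2, content=o2_content(hb, so2, p, curve))

    def is_consistent(self, hb: float, curve: CurveSettings = _DEFAULT_CURVE, tol: float = 1e-4) -> bool:
        """Whether saturation and content agree with PO2 under the curve,
        within ``tol`` mL/dL on content (and the equivalent on saturation)."""
        s = hb_saturation(self.po2, curve)
        c = o2_content(hb, self.so2, self.po2, curve)
        return abs(c - self.content) <= tol and abs(s - self.so2) * curve.hufner * max(hb, 1e-12) <= tol


@dataclass(frozen=True)
class PeakMeasurementRecord:
    """One subject's measured peak iCPET panel.

    Required fields are the peak gas-exchange and hemodynamic measurements the
    pathway analysis consumes; pressures, heart rate and lactate are optional
    pass-through. ``extras`` carries any unmodeled metadata (HCO3, PetCO2, ...).
    """

    subject_id: str
    vo2: float  # mL/min STPD
    vco2: float  # mL/min
    ve: float  # L/min BTPS
    vd_vt: Optional[float]  # fraction of dead space; None when unmeasured
    co: float  # direct-Fick cardiac output, L/min
    hb: float  # g/dL
    arterial: BloodPoint
    paco2: float  # mmHg
    venous: BloodPoint
    rer: float
    mpap: Optional[float] = None
    pcwp: Optional[float] = None
    rap: Optional[float] = None
    hr: Optional[float] = None
    lactate: Optional[float] = None
    rest_mpap: Optional[float] = None
    rest_co: Optional[float] = None
    rest_rap: Optional[float] = None
    rest_pcwp: Optional[float] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.vo2 <= 0:
            raise PhysiologyError("VO2peak must be positive")
        if self.vd_vt is not None and not 0.0 <= self.vd_vt < 1.0:
            raise PhysiologyError("Vd/Vt must lie in [0, 1)")
        if self.co <= 0:
            raise PhysiologyError("cardiac output must be positive")
        if self.hb <= 0:
            raise PhysiologyError("hemoglobin must be positive")
        if self.arterial.so2 < self.venous.so2:
            raise PhysiologyError("arterial saturation below venous saturation")


# ---------------------------------------------------------------------------
# Gas-exchange / hemodynamic primitives
# ---------------------------------------------------------------------------


def hb_saturation(po2: float, curve: CurveSettings = _DEFAULT_CURVE) -> float:
    """Hb O2 saturation (fraction) at the given PO2 under the Severinghaus
    standard curve, S = 1 / (23400 / (P³ + 150 P) + 1), optionally rescaled
    along the PO2 axis by the curve's effective P50."""
    if po2 < 0:
        raise PhysiologyError("PO2 must be non-negative")
    if po2 == 0.0:
        return 0.0
    x = po2 / curve.p50_scale
    u = x * x * x + 150.0 * x
    return u / (u + 23400.0)


def po2_from_saturation(so2: float, curve: CurveSettings = _DEFAULT_CURVE) -> float:
    """Numeric inverse of :func:`hb_saturation` (monotone in S)."""
    if not 0.0 <= so2 < 1.0:
        raise PhysiologyError("saturation must lie in [0, 1); the curve is asymptotic at 1")
    if so2 == 0.0:
        return 0.0
    # x^3 + 150 x = 23400 S / (1 - S); bracket generously then solve.
    rhs = 23400.0 * so2 / (1.0 - so2)
    hi = max(10.0, rhs ** (1.0 / 3.0) + math.sqrt(rhs / 150.0) + 1.0)
    x = brentq(lambda t: t * t * t + 150.0 * t - rhs, 0.0, hi, xtol=1e-12, rtol=8.9e-16)
    return x * curve.p50_scale


def o2_content(hb: float, so2: float, po2: float, curve: CurveSettings = _DEFAULT_CURVE) -> float:
    """Blood O2 content, mL/dL: Hüfner-bound plus dissolved O2."""
    if hb < 0:
        raise PhysiologyError("hemoglobin must be non-negative")
    if not 0.0 <= so2 < 1.0:
        raise PhysiologyError("saturation must lie in [0, 1)")
    if po2 < 0:
        raise PhysiologyError("PO2 must be non-negative")
    return curve.hufner * hb * so2 + curve.solubility * po2


def extraction_ratio(cao2: float, cvo2: float) -> float:
    """Systemic O2 extraction ratio, (CaO2 − CvO2) / CaO2."""
    if cao2 <= 0:
        raise PhysiologyError("arterial O2 content must be positive")
    if cvo2 < 0:
        raise PhysiologyError("venous O2 content must be non-negative")
    return (cao2 - cvo2) / cao2


def alveolar_ventilation(ve: float, vd_vt: float) -> float:
    """Dead-space-corrected alveolar ventilation, V̇a = V̇e · (1 − Vd/Vt), L/min."""
    if ve <= 0:
        raise PhysiologyError("minute ventilation must be positive")
    if not 0.0 <= vd_vt < 1.0:
        raise PhysiologyError("Vd/Vt must lie in [0, 1)")
    return ve * (1.0 - vd_vt)


def alveolar_po2(vo2: float, va: float, env: Environment = Environment()) -> float:
    """Alveolar PO2 from the single-gas O2 mass balance,
    PAO2 = PIO2 − 863 · (V̇O2/1000) / V̇a.

    The respiratory-quotient correction term of the full alveolar gas equation
    is deliberately omitted (single-gas mass-balance form); raises
    :class:`InfeasibleOperatingPoint` when ventilation cannot support the
    requested uptake (PAO2 ≤ 0)."""
    if va <= 0:
        raise PhysiologyError("alveolar ventilation must be positive")
    if vo2 < 0:
        raise PhysiologyError("VO2 must be non-negative")
    pao2 = env.pio2 - ALVEOLAR_GAS_CONSTANT * (vo2 / 1000.0) / va
    if pao2 <= 0:
        raise InfeasibleOperatingPoint(
            f"ventilation {va:g} L/min cannot support VO2 {vo2:g} mL/min (PAO2 <= 0)"
        )
    return pao2


def fick_vo2(q: float, cao2: float, cvo2: float) -> float:
    """Fick principle: V̇O2 = Q̇ · (CaO2 − CvO2) · 10 (dL→L bridge), mL/min."""
    if q <= 0:
        raise PhysiologyError("cardiac output must be positive")
    return 10.0 * q * (cao2 - cvo2)


def fick_q(vo2: float, cao2: float, cvo2: float) -> float:
    """Direct-Fick cardiac output, L/min; inverse of :func:`fick_vo2`."""
    if vo2 <= 0:
        raise PhysiologyError("VO2 must be positive")
    if cao2 <= cvo2:
        raise PhysiologyError("arterial content must exceed venous content")
    return vo2 / (10.0 * (cao2 - cvo2))


def body_surface_area(height: float, weight: float) -> float:
    """DuBois body surface area, m²: 0.007184 · W^0.425 · H^0.725."""
    if height <= 0 or weight <= 0:
        raise PhysiologyError("height and weight must be positive")
    return 0.007184 * weight**0.425 * height**0.725
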