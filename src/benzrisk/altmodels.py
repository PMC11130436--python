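"""Cross-validation models: EPA inhalation unit risk and the Singapore matrix.

EPA route: lifetime risk = IUR × EC, where the exposure concentration
EC = CA·ET·EF·ED/AT time-averages the workplace air level over a lifetime.
The benzene IUR spans (2.2–7.8)×10⁻⁶ per μg/m³, so risks are reported as a
range.

Singapore semi-quantitative route: a hazard rating HR (5 for a confirmed
human carcinogen like benzene) and an exposure rating ER binned from E/OEL
combine into risk value √(HR×ER) on a 1–5 scale with a verbal grade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "EpaInputs",
    "EpaConfig",
    "SingaporeRating",
    "exposure_concentration",
    "epa_risk",
    "epa_risk_range",
    "exposure_rating",
    "singapore_risk",
    "BENZENE_HR",
    "BENZENE_OEL_MG_M3",
]

#: Hazard rating for benzene (confirmed human carcinogen).
BENZENE_HR = 5
#: Chinese occupational exposure limit for benzene, mg/m³.
BENZENE_OEL_MG_M3 = 3.0

RISK_GRADE_LABELS = {
    1: "Negligible risk",
    2: "Low risk",
    3: "Medium risk",
    4: "High risk",
    5: "Very high risk",
}


@dataclass(frozen=True)
class EpaInputs:
    """Inputs of the EPA exposure-concentration calculation.

    ca is in μg/m³; et hours/day; ef days/year; ed years; at hours.
    """

    ca: float
    et: float
    ef: float
    ed: float
    at: float
    iur_low: float = 2.2e-6
    iur_high: float = 7.8e-6

    def __post_init__(self) -> None:
        for name in ("ca", "et", "ef", "ed", "at", "iur_low", "iur_high"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.at <= 0:
            raise ValueError("averaging time must be positive")
        if self.iur_low > self.iur_high:
            raise ValueError("iur_low must not exceed iur_high")
        if self.at < self.et * self.ef * self.ed:
            raise ValueError("averaging time shorter than total exposure hours")


@dataclass(frozen=True)
class EpaConfig:
    """Occupational defaults for the EPA route.

    8-hour shifts, 250 working days/year, lifetime averaging over the
    Chinese life expectancy of 77.93 years, benzene IUR range from IRIS.
    """

    et_h_per_day: float = 8.0
    ef_days_per_year: float = 250.0
    life_expectancy_years: float = 77.93
    iur_low: float = 2.2e-6
    iur_high: float = 7.8e-6

    @property
    def at_hours(self) -> float:
        return self.life_expectancy_years * 365.0 * 24.0


def exposure_concentration(inputs: EpaInputs) -> float:
    """Lifetime-averaged exposure concentration EC = CA·ET·EF·ED/AT, μg/m³."""
    return inputs.ca * inputs.et * inputs.ef * inputs.ed / inputs.at


def epa_risk(ec: float, iur: float) -> float:
    """Lifetime cancer risk = IUR × EC."""
    if ec < 0 or iur < 0:
        raise ValueError("ec and iur must be non-negative")
    return iur * ec


def epa_risk_range(
    c_twa_mg_m3: float, duration_years: float, config: EpaConfig = EpaConfig()
) -> tuple[float, float]:
    """(low, high) EPA lifetime risk for a workplace air level in mg/m³.

    The mg/m³ → μg/m³ conversion happens here; user-facing exposures stay
    in mg/m³ throughout the package.
    """
    inputs = EpaInputs(
        ca=c_twa_mg_m3 * 1000.0,
        et=config.et_h_per_day,
        ef=config.ef_days_per_year,
        ed=duration_years,
        at=config.at_hours,
        iur_low=config.iur_low,
        iur_high=config.iur_high,
    )
    ec = exposure_concentration(inputs)
    return epa_risk(ec, config.iur_low), epa_risk(ec, config.iur_high)


def exposure_rating(e: float, oel: float = BENZENE_OEL_MG_M3) -> int:
    """Bin E/OEL into the 1–5 exposure rating.

    Left-closed bins: [0,0.1) → 1, [0.1,0.5) → 2, [0.5,1) → 3,
    [1,2) → 4, [2,∞) → 5.
    """
    if oel <= 0:
        raise ValueError("OEL must be positive")
    if e < 0:
        raise ValueError("exposure must be non-negative")
    ratio = e / oel
    if ratio < 0.1:
        return 1
    if ratio < 0.5:
        return 2
    if ratio < 1.0:
        return 3
    if ratio < 2.0:
        return 4
    return 5


@dataclass(frozen=True)
class SingaporeRating:
    """Semi-quantitative risk rating: √(HR×ER) with a verbal grade."""

    hr: int
    er: int
    risk_value: float = field(init=False)
    risk_product: int = field(init=False)
    risk_grade: int = field(init=False)
    label: str = field(init=False)

    def __post_init__(self) -> None:
        if self.hr not in range(1, 6) or self.er not in range(1, 6):
            raise ValueError("HR and ER must be integers 1–5")
        value = math.sqrt(self.hr * self.er)
        object.__setattr__(self, "risk_value", value)
        object.__setattr__(self, "risk_product", self.hr * self.er)
        grade = int(round(value))
        object.__setattr__(self, "risk_grade", grade)
        object.__setattr__(self, "label", RISK_GRADE_LABELS[grade])


def singapore_risk(hr: int, er: int) -> SingaporeRating:
    """Combine hazard and exposure ratings into the matrix risk rating.

    The risk value is √(HR×ER) (the geometric-mean convention of the
    Singapore semi-quantitative method); the raw product is also exposed on
    the returned rating.  Grades round the value to the nearest integer.
    """
    return SingaporeRating(hr=hr, er=er)
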