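"""Urinary-biomarker bridge: metabolite ⇄ airborne benzene ⇄ leukemia risk.

Urinary S-phenylmercapturic acid (S-PMA) and trans,trans-muconic acid
(t,t-MA), both in μg/g creatinine, track airborne benzene on the log-log
scale with a smoking adjustment:

    ln(metabolite) = b · ln(C_TWA) + s · SMO + c        (SMO: smoker = 1)

Fitting that regression on paired samples, inverting it at a measured
metabolite value, and pushing the inferred air concentration through the
multistage model yields a biomarker-based leukemia risk — the route used
for workers whose air monitor reads below the detection limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import InversionError, RankDeficiencyError
from .multistage import MultistageResults
from .risk import risk_from_twa

__all__ = [
    "RegressionFit",
    "MetaboliteMeasurement",
    "fit_loglog_regression",
    "predict_ln_metabolite",
    "invert_to_air",
    "risk_from_metabolite",
    "SPMA_PUBLISHED",
    "TTMA_PUBLISHED",
]


@dataclass(frozen=True)
class RegressionFit:
    """Coefficients of the ln-metabolite on ln-air regression."""

    metabolite: str  # "S-PMA" | "t,t-MA"
    slope: float  # b, on ln(C_TWA)
    smoking_coef: float  # s, on the smoker dummy
    intercept: float  # c, ln(μg/g Cr)
    r_squared: float
    resid_sd: float
    n: int
    slope_se: float = float("nan")  # OLS standard error of the slope

    def __post_init__(self) -> None:
        if not 0 <= self.r_squared <= 1:
            raise ValueError("R² must be in [0, 1]")
        if self.resid_sd < 0:
            raise ValueError("residual SD must be non-negative")
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")

    def to_dict(self) -> dict:
        return {
            "metabolite": self.metabolite, "slope": self.slope,
            "smoking_coef": self.smoking_coef, "intercept": self.intercept,
            "r_squared": self.r_squared, "resid_sd": self.resid_sd, "n": self.n,
        }


@dataclass(frozen=True)
class MetaboliteMeasurement:
    """A single creatinine-corrected urinary metabolite value."""

    value: float  # μg/g creatinine
    metabolite: str
    smoker: int = 0

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("metabolite value must be > 0 for log transforms")
        if self.smoker not in (0, 1):
            raise ValueError("smoker flag must be 0 or 1")


#: Published regression of ln(S-PMA) on ln(C_TWA) with smoking adjustment.
SPMA_PUBLISHED = RegressionFit(
    metabolite="S-PMA", slope=0.77, smoking_coef=0.12, intercept=0.54,
    r_squared=0.58, resid_sd=float("nan"), n=217,
)
#: Published regression of ln(t,t-MA) on ln(C_TWA) with smoking adjustment.
TTMA_PUBLISHED = RegressionFit(
    metabolite="t,t-MA", slope=0.68, smoking_coef=0.08, intercept=4.73,
    r_squared=0.45, resid_sd=float("nan"), n=217,
)


def fit_loglog_regression(
    air_benzene, metabolite_values, smoker, metabolite: str
) -> RegressionFit:
    """OLS of ln(metabolite) on ln(air benzene) and the smoker dummy.

    Parameters are sample-level arrays (one entry per valid monitoring
    sample); all concentrations must be strictly positive.
    """
    air = np.asarray(air_benzene, dtype=float)
    met = np.asarray(metabolite_values, dtype=float)
    smo = np.asarray(smoker, dtype=float)
    if air.size < 10:
        raise ValueError(f"need >= 10 samples, got {air.size}")
    if np.any(air <= 0) or np.any(met <= 0):
        raise ValueError("air and metabolite values must be > 0")
    X = sm.add_constant(pd.DataFrame({"ln_air": np.log(air), "smoker": smo}))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise RankDeficiencyError(
            "design matrix rank deficient (constant regressor, e.g. no smokers)"
        )
    res = sm.OLS(np.log(met), X).fit()
    resid_sd = float(np.sqrt(res.scale)) if res.df_resid > 0 else 0.0
    return RegressionFit(
        metabolite=metabolite,
        slope=float(res.params["ln_air"]),
        smoking_coef=float(res.params["smoker"]),
        intercept=float(res.params["const"]),
        r_squared=min(max(float(res.rsquared), 0.0), 1.0),
        resid_sd=resid_sd,
        n=int(res.nobs),
        slope_se=float(res.bse["ln_air"]),
    )


def fit_loglog_from_frame(df: pd.DataFrame, metabolite: str) -> RegressionFit:
    """Fit from a sample frame with the standard column names.

    Expects ``air_benzene_mg_m3``, ``smoker`` and either ``spma_ug_gcr`` or
    ``ttma_ug_gcr`` depending on ``metabolite`` ("S-PMA" or "t,t-MA").
    """
    col = {"S-PMA": "spma_ug_gcr", "t,t-MA": "ttma_ug_gcr"}[metabolite]
    return fit_loglog_regression(
        df["air_benzene_mg_m3"], df[col], df["smoker"], metabolite
    )


def predict_ln_metabolite(fit: RegressionFit, c_twa: float, smoker: int) -> float:
    """b·ln(c_twa) + s·SMO + c, the regression's mean prediction."""
    if c_twa <= 0:
        raise ValueError("c_twa must be > 0")
    return fit.slope * np.log(c_twa) + fit.smoking_coef * smoker + fit.intercept


def invert_to_air(fit: RegressionFit, m: MetaboliteMeasurement) -> float:
    """Air benzene concentration implied by a metabolite measurement.

    Solves the regression for C_TWA: exp[(ln m − s·SMO − c) / b].  Exactly
    round-trips :func:`predict_ln_metabolite`.
    """
    if fit.slope == 0:
        raise InversionError("zero slope: metabolite carries no air information")
    return float(
        np.exp((np.log(m.value) - fit.smoking_coef * m.smoker - fit.intercept) / fit.slope)
    )


def risk_from_metabolite(
    lms: MultistageResults,
    fit: RegressionFit,
    m: MetaboliteMeasurement,
    t: float,
) -> float:
    """Leukemia risk from a urinary metabolite value and working duration.

    Composition of the inverse regression with the multistage curve:
    P(invert_to_air(fit, m) × t).
    """
    if t < 0:
        raise ValueError("duration must be non-negative")
    return float(risk_from_twa(lms, invert_to_air(fit, m), t))
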