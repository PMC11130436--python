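"""Quantal multistage dose-response model for grouped cohort incidence data.

The model is the classic linearized multistage (LMS) form used for cancer
risk assessment,

    P(d) = r + (1 - r) * (1 - exp(-(a_1 d + a_2 d^2 + ... + a_k d^k)))

with background response ``r`` in [0, 1) and non-negative stage coefficients
``a_i``.  Given grouped data (dose midpoint, subjects, cases) the parameters
are estimated by constrained binomial maximum likelihood, mirroring the
behaviour of EPA's BMDS multistage-dichotomous fitter.  Fit quality is judged
by a Pearson chi-square test on the grouped counts.

The public surface follows the statsmodels convention: build a
:class:`MultistageModel` from data, call :meth:`~MultistageModel.fit`, and
work with the returned :class:`MultistageResults`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .exceptions import (
    ConvergenceError,
    IdentifiabilityError,
    ReferenceGroupError,
    SaturatedModelError,
)

__all__ = [
    "DoseGroup",
    "CohortSummary",
    "MultistageModel",
    "MultistageResults",
    "GofResult",
    "multistage_probability",
    "summarize_cohort",
    "fit_multistage",
    "select_degree",
    "load_cohort_csv",
    "chinese_benzene_cohort",
    "PUBLISHED_LMS",
]

_PROB_EPS = 1e-300


@dataclass(frozen=True)
class DoseGroup:
    """One exposure stratum of a grouped cohort.

    Parameters
    ----------
    dose_midpoint : float
        Midpoint of cumulative benzene exposure for the stratum, mg/m³·year.
    n_subjects : int
        Number of cohort members in the stratum.
    n_cases : int
        Number of leukemia cases observed in the stratum.
    """

    dose_midpoint: float
    n_subjects: int
    n_cases: int

    def __post_init__(self) -> None:
        if self.dose_midpoint < 0:
            raise ValueError(f"dose_midpoint must be >= 0, got {self.dose_midpoint}")
        if self.n_subjects <= 0:
            raise ValueError(f"n_subjects must be > 0, got {self.n_subjects}")
        if not 0 <= self.n_cases <= self.n_subjects:
            raise ValueError(
                f"n_cases must lie in [0, n_subjects], got {self.n_cases}/{self.n_subjects}"
            )

    @property
    def incidence(self) -> float:
        return self.n_cases / self.n_subjects


@dataclass(frozen=True)
class CohortSummary:
    """Per-group incidence and relative risk versus the zero-dose stratum."""

    dose_midpoints: np.ndarray
    incidence: np.ndarray
    relative_risk: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dose_midpoint": self.dose_midpoints,
                "incidence": self.incidence,
                "relative_risk": self.relative_risk,
            }
        )


@dataclass(frozen=True)
class GofResult:
    """Pearson chi-square goodness of fit for a grouped quantal fit."""

    chi_square: float
    df: int
    p_value: float
    deviance: float


def summarize_cohort(groups: Sequence[DoseGroup]) -> CohortSummary:
    """Crude incidence and relative risk per dose group.

    The zero-dose group is the reference; its RR is 1 by construction.  If
    the reference has zero cases, RRs of the exposed groups are undefined and
    reported as ``inf`` (the reference itself keeps RR 1 by convention).
    """
    groups = list(groups)
    ref = [g for g in groups if g.dose_midpoint == 0]
    if not ref:
        raise ReferenceGroupError("no zero-dose group: relative risk reference undefined")
    ref_inc = ref[0].incidence
    inc = np.array([g.incidence for g in groups], dtype=float)
    dose = np.array([g.dose_midpoint for g in groups], dtype=float)
    if ref_inc > 0:
        rr = inc / ref_inc
    else:
        rr = np.where(inc > 0, np.inf, 1.0)
    rr = np.where(dose == 0, 1.0, rr)
    return CohortSummary(dose_midpoints=dose, incidence=inc, relative_risk=rr)


def multistage_probability(
    r: float, coefficients: Sequence[float], dose: float | np.ndarray
) -> float | np.ndarray:
    """Evaluate P(d) = r + (1-r)(1 - exp(-sum_i a_i d^i)).

    ``coefficients`` holds (a_1, ..., a_k).  Vectorized over ``dose``.
    """
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    a = np.asarray(coefficients, dtype=float)
    powers = np.arange(1, a.size + 1)
    s = (a * d[..., None] ** powers).sum(axis=-1)
    p = r + (1.0 - r) * (-np.expm1(-s))
    if np.isscalar(dose) or np.ndim(dose) == 0:
        return float(p)
    return p


class MultistageModel:
    """Quantal multistage model for grouped (dose, subjects, cases) data.

    Parameters
    ----------
    groups : sequence of DoseGroup
        At least two dose strata.
    degree : int
        Polynomial degree k of the dose term (number of stage coefficients).
    """

    def __init__(self, groups: Sequence[DoseGroup], degree: int = 1):
        groups = list(groups)
        if len(groups) < 2:
            raise IdentifiabilityError("need at least 2 dose groups")
        if degree < 1:
            raise ValueError("degree must be >= 1")
        if degree + 1 > len(groups):
            raise IdentifiabilityError(
                f"degree {degree} needs {degree + 1} parameters but only "
                f"{len(groups)} groups are available"
            )
        self.groups = groups
        self.degree = degree
        self.dose = np.array([g.dose_midpoint for g in groups], dtype=float)
        self.n = np.array([g.n_subjects for g in groups], dtype=float)
        self.y = np.array([g.n_cases for g in groups], dtype=float)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, degree: int = 1) -> "MultistageModel":
        """Build from a frame with columns dose_midpoint, n_subjects, n_cases."""
        groups = [
            DoseGroup(float(row.dose_midpoint), int(row.n_subjects), int(row.n_cases))
            for row in df.itertuples()
        ]
        return cls(groups, degree=degree)

    # -- likelihood ---------------------------------------------------------

    def loglike(self, r: float, coefficients: Sequence[float]) -> float:
        """Binomial log-likelihood of the grouped counts at (r, a)."""
        p = np.clip(
            multistage_probability(r, coefficients, self.dose), _PROB_EPS, 1 - 1e-12
        )
        return float((self.y * np.log(p) + (self.n - self.y) * np.log1p(-p)).sum())

    def _nll_raw(self, params: np.ndarray) -> float:
        r, a = params[0], params[1:]
        if not (0 <= r < 1) or np.any(a < 0):
            return np.inf
        return -self.loglike(r, a)

    def _nll_transformed(self, theta: np.ndarray) -> float:
        # theta = (logit r, log a_1, ..., log a_k): unconstrained scale
        r = expit(theta[0])
        a = np.exp(theta[1:])
        return -self.loglike(r, a)

    def _starts(self) -> list[np.ndarray]:
        """Deterministic multi-start points on the transformed scale."""
        props = self.y / self.n
        pooled = max(self.y.sum() / self.n.sum(), 1e-8)
        zero_mask = self.dose == 0
        r_bg = float(props[zero_mask][0]) if zero_mask.any() else float(props.min())
        r_bg = max(r_bg, 1e-8)
        dmax = self.dose.max()
        spread = max(props.max() - props.min(), 1e-8)
        a_slope = max(spread / max(dmax, 1.0), 1e-12)
        starts = []
        for r0 in (r_bg, pooled):
            for a_scale in (1.0, 0.1, 10.0):
                theta = np.empty(1 + self.degree)
                theta[0] = logit(min(r0, 1 - 1e-9))
                for i in range(self.degree):
                    theta[1 + i] = np.log(a_slope * a_scale / max(dmax, 1.0) ** i)
                starts.append(theta)
        return starts[:6]

    def _saturated_solution(self) -> np.ndarray | None:
        """Exact parameters when #groups == degree+1 and a zero-dose group exists.

        With as many parameters as groups the MLE interpolates the observed
        proportions whenever they are non-decreasing in dose; solve directly.
        """
        if len(self.groups) != self.degree + 1:
            return None
        order = np.argsort(self.dose)
        d, props = self.dose[order], (self.y / self.n)[order]
        if d[0] != 0 or np.any(np.diff(props) < 0) or np.any(props >= 1):
            return None
        r = props[0]
        if r >= 1:
            return None
        # -ln((1-P)/(1-r)) = sum_i a_i d^i : Vandermonde solve on exposed rows
        rhs = -np.log((1 - props[1:]) / (1 - r))
        vand = d[1:, None] ** np.arange(1, self.degree + 1)
        try:
            a = np.linalg.solve(vand, rhs)
        except np.linalg.LinAlgError:
            return None
        if np.any(a < 0):
            return None
        return np.concatenate([[r], a])

    def fit(self) -> "MultistageResults":
        """Constrained maximum-likelihood fit.

        Runs Nelder-Mead from several deterministic starts on an
        unconstrained reparameterisation (logit r, log a_i), polishes the
        best candidate with box-constrained L-BFGS-B on the raw scale so
        boundary solutions (a_i = 0, r = 0) are reachable exactly, and checks
        the closed-form interpolating solution when the model is saturated.
        """
        if self.y.sum() == 0:
            warnings.warn("all groups have zero cases: r pinned to 0", stacklevel=2)
            params = np.zeros(1 + self.degree)
            return self._make_results(params, converged=True)

        best_theta, best_val, any_ok = None, np.inf, False
        for theta0 in self._starts():
            res = optimize.minimize(
                self._nll_transformed,
                theta0,
                method="Nelder-Mead",
                options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 20000},
            )
            if res.fun < best_val:
                best_theta, best_val = res.x, res.fun
                any_ok = any_ok or res.success
        if best_theta is None:
            raise ConvergenceError("all optimizer starts failed")

        raw0 = np.concatenate([[expit(best_theta[0])], np.exp(best_theta[1:])])
        bounds = [(0.0, 1.0 - 1e-10)] + [(0.0, None)] * self.degree
        polish = optimize.minimize(
            self._nll_raw, raw0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 5000},
        )
        params = polish.x if polish.fun <= best_val else raw0
        converged = any_ok or polish.success

        sat = self._saturated_solution()
        if sat is not None and self._nll_raw(sat) <= self._nll_raw(params) + 1e-12:
            params, converged = sat, True
        return self._make_results(params, converged=converged)

    def _make_results(self, params: np.ndarray, converged: bool) -> "MultistageResults":
        r, a = float(params[0]), np.asarray(params[1:], dtype=float)
        return MultistageResults(
            model=self, degree=self.degree, r=r, coefficients=a,
            log_likelihood=self.loglike(r, a), converged=converged,
        )


@dataclass(frozen=True)
class MultistageResults:
    """Fitted (or externally supplied) multistage model parameters.

    Attributes
    ----------
    r : float
        Background response level; P(0) = r.
    coefficients : ndarray
        Stage coefficients (a_1, ..., a_k), units (mg/m³·year)^-i.
    log_likelihood : float
        Binomial log-likelihood at the estimate (nan for external parameters).
    """

    degree: int
    r: float
    coefficients: np.ndarray
    log_likelihood: float
    converged: bool
    model: MultistageModel | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.r < 1:
            raise ValueError(f"background r must be in [0, 1), got {self.r}")
        if np.any(np.asarray(self.coefficients) < 0):
            raise ValueError("stage coefficients must be non-negative")

    @classmethod
    def from_params(
        cls, r: float, coefficients: Sequence[float]
    ) -> "MultistageResults":
        """Wrap externally known parameters (e.g. a published fit)."""
        a = np.asarray(coefficients, dtype=float)
        return cls(
            degree=a.size, r=float(r), coefficients=a,
            log_likelihood=float("nan"), converged=True, model=None,
        )

    @property
    def a1(self) -> float:
        return float(self.coefficients[0])

    def predict(self, dose: float | np.ndarray) -> float | np.ndarray:
        """Lifetime leukemia probability at cumulative exposure ``dose``."""
        return multistage_probability(self.r, self.coefficients, dose)

    def gof(self) -> GofResult:
        """Pearson chi-square goodness of fit against the grouped counts.

        df = (#groups) - (#estimated parameters); coefficients at the a_i = 0
        boundary still count as estimated.  Deviance is reported alongside as
        a secondary statistic.
        """
        if self.model is None:
            raise ValueError("no data attached: GOF requires a fitted model")
        m = self.model
        df = len(m.groups) - (self.degree + 1)
        if df <= 0:
            raise SaturatedModelError(
                f"{len(m.groups)} groups, {self.degree + 1} parameters: GOF p undefined"
            )
        p = np.clip(np.asarray(self.predict(m.dose)), 1e-300, 1 - 1e-12)
        expected = m.n * p
        chi2 = float((((m.y - expected) ** 2) / (expected * (1 - p))).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            term1 = np.where(m.y > 0, m.y * np.log(m.y / expected), 0.0)
            term0 = np.where(
                m.n - m.y > 0, (m.n - m.y) * np.log((m.n - m.y) / (m.n - expected)), 0.0
            )
        deviance = float(2 * (term1 + term0).sum())
        return GofResult(
            chi_square=chi2, df=df, p_value=float(stats.chi2.sf(chi2, df)),
            deviance=deviance,
        )

    def summary(self) -> str:
        """Plain-text summary table in the spirit of statsmodels results."""
        lines = [
            "Quantal multistage model (grouped binomial MLE)",
            "=" * 52,
            f"degree:          {self.degree}",
            f"background r:    {self.r:.6g}",
        ]
        for i, a in enumerate(self.coefficients, start=1):
            lines.append(f"a_{i}:             {a:.6g}")
        lines.append(f"log-likelihood:  {self.log_likelihood:.6f}")
        lines.append(f"converged:       {self.converged}")
        if self.model is not None and len(self.model.groups) > self.degree + 1:
            g = self.gof()
            lines.append(
                f"GOF chi2={g.chi_square:.4f}, df={g.df}, p={g.p_value:.4f} "
                f"(deviance {g.deviance:.4f})"
            )
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        out = {
            "degree": self.degree,
            "r": self.r,
            "a": list(map(float, self.coefficients)),
            "loglik": self.log_likelihood,
            "converged": self.converged,
        }
        if self.model is not None and len(self.model.groups) > self.degree + 1:
            g = self.gof()
            out["gof"] = {"chi2": g.chi_square, "df": g.df, "p": g.p_value}
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "MultistageResults":
        with open(path) as fh:
            d = json.load(fh)
        a = np.asarray(d["a"], dtype=float)
        return cls(
            degree=int(d["degree"]), r=float(d["r"]), coefficients=a,
            log_likelihood=float(d.get("loglik", float("nan"))),
            converged=bool(d.get("converged", True)), model=None,
        )


def fit_multistage(groups: Iterable[DoseGroup], degree: int = 1) -> MultistageResults:
    """Convenience wrapper: build the model and fit in one call."""
    return MultistageModel(list(groups), degree=degree).fit()


def select_degree(groups: Iterable[DoseGroup], max_degree: int = 1) -> MultistageResults:
    """Fit degrees 1..max_degree, return the one with the best GOF p-value.

    Degrees that saturate the data (df <= 0) cannot be scored and are
    skipped; ties break toward the lowest degree.
    """
    groups = list(groups)
    best, best_p = None, -np.inf
    errors = []
    for k in range(1, max_degree + 1):
        try:
            fit = fit_multistage(groups, degree=k)
            p = fit.gof().p_value
        except (IdentifiabilityError, SaturatedModelError, ConvergenceError) as exc:
            errors.append((k, exc))
            continue
        if p > best_p + 1e-12:
            best, best_p = fit, p
    if best is None:
        raise ConvergenceError(f"no degree in 1..{max_degree} produced a scorable fit: {errors}")
    return best


def load_cohort_csv(path) -> list[DoseGroup]:
    """Read a grouped-cohort CSV with columns dose_midpoint,n_subjects,n_cases."""
    df = pd.read_csv(path)
    required = {"dose_midpoint", "n_subjects", "n_cases"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return [
        DoseGroup(float(r.dose_midpoint), int(r.n_subjects), int(r.n_cases))
        for r in df.itertuples()
    ]


def chinese_benzene_cohort() -> list[DoseGroup]:
    """Grouped leukemia incidence of the Chinese benzene cohort (bundled).

    Three strata: unexposed, <130 and 130-646 mg/m³·year of cumulative
    benzene exposure, with doses entered at the stratum midpoints.
    """
    with resources.files("benzrisk.data").joinpath("chinese_cohort_table1.csv").open() as fh:
        return load_cohort_csv(fh)


#: Published degree-1 LMS model for benzene-induced leukemia
#: (r = 4.32e-4, a1 = 1.38e-6 per mg/m³·year), as fitted to the Chinese
#: benzene cohort.  Used where downstream results must be anchored to the
#: printed parameter values rather than a refit.
PUBLISHED_LMS = MultistageResults.from_params(r=4.32e-4, coefficients=[1.38e-6])
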