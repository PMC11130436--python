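"""Turn worker exposure assignments into multistage leukemia risks.

Cumulative exposure is Dc = C_TWA × T (time-weighted-average airborne
benzene times working duration), so the lifetime risk of a worker follows
directly from the fitted multistage curve evaluated at Dc.  Group summaries
average per-worker risks and attach a t-interval; an ANOVA linear-contrast
trend test checks whether risk rises across ordered exposure groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .multistage import MultistageResults

__all__ = [
    "GROUP_BOUNDARIES",
    "GROUP_LABELS",
    "ExposureAssignment",
    "RiskEstimate",
    "TrendResult",
    "risk_from_twa",
    "excess_and_extra_risk",
    "group_risk_summary",
    "trend_test",
]

#: Rounded quartile boundaries of cumulative exposure, mg/m³·year.
GROUP_BOUNDARIES: tuple[float, ...] = (3.0, 5.0, 12.0)
#: Group labels for the half-open bins [0,3), [3,5), [5,12), [12,inf).
GROUP_LABELS: tuple[str, ...] = ("<3", "3–5", "5–12", "≥12")


@dataclass(frozen=True)
class ExposureAssignment:
    """A worker's aggregated exposure: C_TWA, duration, and their product Dc."""

    worker_id: str
    c_twa: float  # mg/m³, mean over valid monitoring rounds
    duration: float  # years
    group_label: str | None = None
    smoker: int = 0
    dc: float = field(init=False)

    def __post_init__(self) -> None:
        if self.c_twa < 0 or self.duration < 0:
            raise ValueError("c_twa and duration must be non-negative")
        object.__setattr__(self, "dc", self.c_twa * self.duration)


@dataclass(frozen=True)
class RiskEstimate:
    """A model-tagged group risk with interval and provenance."""

    model_tag: str  # LMS-air | LMS-SPMA | LMS-ttMA | EPA | Singapore
    group_label: str
    point: float
    ci_low: float
    ci_high: float
    n: int

    def __post_init__(self) -> None:
        if not (np.isnan(self.ci_low) or self.ci_low <= self.point <= self.ci_high):
            raise ValueError("interval must bracket the point estimate")


@dataclass(frozen=True)
class TrendResult:
    statistic: float
    p_value: float
    df: tuple[int, int]


def risk_from_twa(fit: MultistageResults, c_twa, t):
    """Lifetime leukemia risk after ``t`` years at airborne level ``c_twa``.

    Only the product Dc = c_twa * t enters the model.
    """
    c = np.asarray(c_twa, dtype=float)
    ty = np.asarray(t, dtype=float)
    if np.any(c < 0) or np.any(ty < 0):
        raise ValueError("c_twa and t must be non-negative")
    return fit.predict(c * ty)


def excess_and_extra_risk(fit: MultistageResults, dose) -> tuple:
    """Added risk P(d) - r and extra risk (P(d) - r) / (1 - r)."""
    p = fit.predict(dose)
    added = p - fit.r
    return added, added / (1.0 - fit.r)


def group_risk_summary(
    workers: Sequence[ExposureAssignment],
    fit: MultistageResults,
    model_tag: str = "LMS-air",
    conf_level: float = 0.95,
    group_order: Sequence[str] = GROUP_LABELS,
) -> list[RiskEstimate]:
    """Per-group mean risk with a t-interval on the worker-level risks.

    Groups with a single worker get a NaN interval (flagged, not hidden).
    """
    if any(w.group_label is None for w in workers):
        raise ValueError("every worker must carry a group label")
    out = []
    for label in group_order:
        risks = np.array(
            [risk_from_twa(fit, w.c_twa, w.duration) for w in workers if w.group_label == label]
        )
        if risks.size == 0:
            continue
        point = float(risks.mean())
        if risks.size >= 2:
            se = risks.std(ddof=1) / np.sqrt(risks.size)
            tcrit = stats.t.ppf(0.5 + conf_level / 2, risks.size - 1)
            lo, hi = point - tcrit * se, point + tcrit * se
        else:
            lo = hi = float("nan")
        out.append(
            RiskEstimate(
                model_tag=model_tag, group_label=label, point=point,
                ci_low=float(lo), ci_high=float(hi), n=int(risks.size),
            )
        )
    return out


def trend_test(group_values: Sequence[Sequence[float]]) -> TrendResult:
    """ANOVA linear-trend test across ordered groups.

    Uses equally spaced scores over group rank; the linear-contrast sum of
    squares is tested against the pooled within-group mean square with an F
    test on (1, N - k) degrees of freedom (equivalent to a two-sided t test
    on the contrast).
    """
    groups = [np.asarray(g, dtype=float) for g in group_values]
    if len(groups) < 3:
        raise ValueError("need >= 3 ordered groups for a trend test")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group in trend test")
    k = len(groups)
    ns = np.array([g.size for g in groups])
    means = np.array([g.mean() for g in groups])
    scores = np.arange(k, dtype=float)
    c = scores - scores.mean()
    contrast = float((c * means).sum())
    ss_contrast = contrast**2 / float((c**2 / ns).sum())
    n_total = int(ns.sum())
    df_err = n_total - k
    if df_err <= 0:
        raise ValueError("no residual degrees of freedom")
    sse = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    mse = sse / df_err
    if ss_contrast == 0:
        return TrendResult(statistic=0.0, p_value=1.0, df=(1, df_err))
    if mse == 0:
        return TrendResult(statistic=float("inf"), p_value=0.0, df=(1, df_err))
    f = ss_contrast / mse
    return TrendResult(
        statistic=float(f), p_value=float(stats.f.sf(f, 1, df_err)), df=(1, df_err)
    )


def risk_table(estimates: Sequence[RiskEstimate], scale: float = 1e4) -> pd.DataFrame:
    """Tabulate risk estimates, adding the display columns in 10^-4 units."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "model": e.model_tag,
                "group": e.group_label,
                "n": e.n,
                "risk": e.point,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "risk_1e4": round(e.point * scale, 2),
                "ci_1e4": f"{e.ci_low * scale:.2f}–{e.ci_high * scale:.2f}",
            }
        )
    return pd.DataFrame(rows)
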