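"""End-to-end orchestration: samples → QC → risks → comparison tables.

Functions here glue the QC, multistage, biomarker and alternative-model
pieces into the tables a risk assessor actually wants: a per-group leukemia
risk table by airborne benzene and by each urinary metabolite (with trend
tests and a biomarker-only row for below-detection workers), and a
three-model comparison table (multistage vs EPA unit-risk vs Singapore
matrix).  The CLI wraps these functions thinly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .altmodels import (
    BENZENE_HR,
    BENZENE_OEL_MG_M3,
    EpaConfig,
    epa_risk_range,
    exposure_rating,
    singapore_risk,
)
from .biomarker import (
    MetaboliteMeasurement,
    RegressionFit,
    SPMA_PUBLISHED,
    TTMA_PUBLISHED,
    invert_to_air,
    risk_from_twa,
)
from .multistage import MultistageResults
from .qc import QcReport, Sample, WorkerRecord, aggregate_worker, assign_groups, qc_filter
from .risk import GROUP_LABELS, ExposureAssignment, trend_test

__all__ = [
    "load_samples_csv",
    "samples_to_workers",
    "assess_workers",
    "assess_samples",
    "compare_models",
    "run_manifest",
]

SAMPLE_COLUMNS = {
    "worker_id", "sample_round", "air_benzene_mg_m3", "spma_ug_gcr",
    "ttma_ug_gcr", "creatinine_g_l", "smoker", "duration_years",
}


def load_samples_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = SAMPLE_COLUMNS - set(df.columns)
    if missing:
        raise ValueError(f"sample CSV missing columns: {sorted(missing)}")
    return df


def samples_to_workers(df: pd.DataFrame) -> list[WorkerRecord]:
    """Reassemble WorkerRecord objects from the long per-sample frame."""
    workers = []
    for wid, sub in df.groupby("worker_id", sort=True):
        samples = tuple(
            Sample(
                worker_id=str(wid),
                sample_round=int(r.sample_round),
                air_benzene=float(r.air_benzene_mg_m3),
                spma=float(r.spma_ug_gcr),
                ttma=float(r.ttma_ug_gcr),
                creatinine=None if pd.isna(r.creatinine_g_l) else float(r.creatinine_g_l),
            )
            for r in sub.itertuples()
        )
        workers.append(
            WorkerRecord(
                worker_id=str(wid), samples=samples,
                smoker=int(sub["smoker"].iloc[0]),
                duration=float(sub["duration_years"].iloc[0]),
            )
        )
    return workers


@dataclass(frozen=True)
class AssessmentResult:
    """Outcome of a worker-panel assessment."""

    table: pd.DataFrame  # per-group risk rows + total (+ below-LOD row)
    trend_p: dict  # model tag -> trend p-value
    qc_report: QcReport | None
    n_biomarker_only: int


def _group_stats(values: np.ndarray, conf: float = 0.95) -> tuple[float, float, float]:
    from scipy import stats

    point = float(values.mean())
    if values.size >= 2:
        se = values.std(ddof=1) / np.sqrt(values.size)
        t = stats.t.ppf(0.5 + conf / 2, values.size - 1)
        return point, point - t * se, point + t * se
    return point, float("nan"), float("nan")


def _worker_metabolite_air(
    worker_samples: Sequence[Sample], fit: RegressionFit, which: str, smoker: int
) -> float:
    """Worker-level air estimate from a metabolite: mean of per-sample inversions."""
    vals = []
    for s in worker_samples:
        raw = s.spma if which == "spma" else s.ttma
        if raw > 0:
            vals.append(
                invert_to_air(fit, MetaboliteMeasurement(raw, fit.metabolite, smoker))
            )
    return float(np.mean(vals)) if vals else float("nan")


def assess_workers(
    workers: Sequence[WorkerRecord],
    lms: MultistageResults,
    spma_fit: RegressionFit = SPMA_PUBLISHED,
    ttma_fit: RegressionFit = TTMA_PUBLISHED,
    group_order: Sequence[str] = GROUP_LABELS,
) -> AssessmentResult:
    """QC the panel and produce the per-group risk table.

    Risks by airborne benzene use each worker's mean valid air sample times
    duration; risks by metabolite invert the (published, by default)
    regression per sample, average the implied air level per worker, and
    evaluate the same multistage curve.  Workers with no detectable air
    sample are summarised in a separate biomarker-only row via t,t-MA.
    """
    all_samples = [s for w in workers for s in w.samples]
    valid, below, report = qc_filter(all_samples)

    assignments: list[ExposureAssignment] = []
    extra: dict[str, dict] = {}
    biomarker_only: list[WorkerRecord] = []
    for w in workers:
        assignment = aggregate_worker(w, valid)
        if assignment is None:
            biomarker_only.append(w)
            continue
        assignments.append(assignment)
        own_valid = [s for s in valid if s.worker_id == w.worker_id]
        extra[w.worker_id] = {
            "air_spma": _worker_metabolite_air(own_valid, spma_fit, "spma", w.smoker),
            "air_ttma": _worker_metabolite_air(own_valid, ttma_fit, "ttma", w.smoker),
            "duration": w.duration,
        }
    assignments = assign_groups(assignments)

    rows = []
    per_model_groups: dict[str, list[np.ndarray]] = {"air": [], "spma": [], "ttma": []}
    for label in group_order:
        members = [a for a in assignments if a.group_label == label]
        if not members:
            continue
        dcs = np.array([a.dc for a in members])
        risks = {
            "air": np.array([float(risk_from_twa(lms, a.c_twa, a.duration)) for a in members]),
            "spma": np.array(
                [
                    float(risk_from_twa(lms, extra[a.worker_id]["air_spma"], a.duration))
                    for a in members
                    if np.isfinite(extra[a.worker_id]["air_spma"])
                ]
            ),
            "ttma": np.array(
                [
                    float(risk_from_twa(lms, extra[a.worker_id]["air_ttma"], a.duration))
                    for a in members
                    if np.isfinite(extra[a.worker_id]["air_ttma"])
                ]
            ),
        }
        row = {"group": label, "n": len(members), "avg_ce": float(dcs.mean())}
        for tag, vals in risks.items():
            if vals.size:
                point, lo, hi = _group_stats(vals)
                per_model_groups[tag].append(vals)
                row[f"risk_{tag}"] = point
                row[f"risk_{tag}_lo"] = lo
                row[f"risk_{tag}_hi"] = hi
                row[f"risk_{tag}_1e4"] = round(point * 1e4, 2)
            else:
                row[f"risk_{tag}"] = float("nan")
        rows.append(row)

    # total row over all grouped workers
    if assignments:
        tot_air = np.array(
            [float(risk_from_twa(lms, a.c_twa, a.duration)) for a in assignments]
        )
        point, lo, hi = _group_stats(tot_air)
        rows.append(
            {
                "group": "Total", "n": len(assignments),
                "avg_ce": float(np.mean([a.dc for a in assignments])),
                "risk_air": point, "risk_air_lo": lo, "risk_air_hi": hi,
                "risk_air_1e4": round(point * 1e4, 2),
            }
        )

    # below-LOD workers: t,t-MA-only row (median metabolite, mean duration)
    if biomarker_only:
        med_ttma = float(
            np.median([s.ttma for w in biomarker_only for s in w.samples if s.ttma > 0])
        )
        mean_t = float(np.mean([w.duration for w in biomarker_only]))
        air = invert_to_air(
            ttma_fit, MetaboliteMeasurement(med_ttma, ttma_fit.metabolite, 0)
        )
        risk = float(risk_from_twa(lms, air, mean_t))
        rows.append(
            {
                "group": "below-LOD", "n": len(biomarker_only), "avg_ce": air * mean_t,
                "risk_ttma": risk, "risk_ttma_1e4": round(risk * 1e4, 2),
            }
        )

    trend_p = {}
    for tag, groups in per_model_groups.items():
        if len(groups) >= 3:
            trend_p[tag] = trend_test(groups).p_value
    return AssessmentResult(
        table=pd.DataFrame(rows), trend_p=trend_p, qc_report=report,
        n_biomarker_only=len(biomarker_only),
    )


def assess_samples(df: pd.DataFrame, lms: MultistageResults, **kwargs) -> AssessmentResult:
    """Assess straight from the per-sample frame."""
    return assess_workers(samples_to_workers(df), lms, **kwargs)


def compare_models(
    group_exposures: pd.DataFrame,
    lms: MultistageResults,
    epa: EpaConfig = EpaConfig(),
    hr: int = BENZENE_HR,
    oel: float = BENZENE_OEL_MG_M3,
    singapore_e: str = "ce_over_duration",
) -> pd.DataFrame:
    """Three-model comparison table from per-group exposure summaries.

    ``group_exposures`` needs columns group, n, c_twa (mg/m³), avg_ce
    (mg/m³·year) and duration (years).  Returns one row per group with the
    multistage risk at the group's average cumulative exposure, the EPA
    IUR-range risk, and the Singapore matrix rating.

    ``singapore_e`` picks the exposure dose E entering the matrix's E/OEL
    ratio: ``"ce_over_duration"`` (default) uses the cumulative-exposure-
    consistent air level avg_ce / duration, which weights each worker's air
    level by exposure time; ``"c_twa"`` uses the plain group mean air level.
    The two differ when air level and duration covary across workers.
    """
    if singapore_e not in ("ce_over_duration", "c_twa"):
        raise ValueError("singapore_e must be 'ce_over_duration' or 'c_twa'")
    rows = []
    for rec in group_exposures.itertuples():
        lms_risk = float(lms.predict(rec.avg_ce))
        lo, hi = epa_risk_range(rec.c_twa, rec.duration, epa)
        e_dose = (
            rec.avg_ce / rec.duration if singapore_e == "ce_over_duration" else rec.c_twa
        )
        rating = singapore_risk(hr, exposure_rating(e_dose, oel))
        rows.append(
            {
                "group": rec.group,
                "n": rec.n,
                "c_twa": rec.c_twa,
                "avg_ce": rec.avg_ce,
                "lms_risk": lms_risk,
                "lms_risk_1e4": round(lms_risk * 1e4, 2),
                "epa_risk_low": lo,
                "epa_risk_high": hi,
                "epa_range_1e4": f"{lo * 1e4:.1f}~{hi * 1e4:.1f}",
                "singapore_e": e_dose,
                "singapore_er": rating.er,
                "singapore_value": round(rating.risk_value, 2),
                "singapore_label": rating.label,
            }
        )
    return pd.DataFrame(rows)


def group_exposures_from_assignments(
    assignments: Sequence[ExposureAssignment],
    group_order: Sequence[str] = GROUP_LABELS,
) -> pd.DataFrame:
    """Summarise labelled workers into the compare_models input frame."""
    rows = []
    for label in group_order:
        members = [a for a in assignments if a.group_label == label]
        if not members:
            continue
        rows.append(
            {
                "group": label,
                "n": len(members),
                "c_twa": float(np.mean([a.c_twa for a in members])),
                "avg_ce": float(np.mean([a.dc for a in members])),
                "duration": float(np.mean([a.duration for a in members])),
            }
        )
    return pd.DataFrame(rows)


def run_manifest(inputs: dict, config: dict, seed: int | None = None) -> dict:
    """Provenance block written next to every pipeline output."""
    digests = {}
    for name, path in inputs.items():
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            h.update(fh.read())
        digests[name] = h.hexdigest()
    return {
        "package": "benzrisk",
        "version": __version__,
        "inputs_sha256": digests,
        "config": config,
        "seed": seed,
        "created_utc": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }
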