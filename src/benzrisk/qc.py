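"""Sample validation and per-worker exposure aggregation.

Raw monitoring data arrive as 1–3 samples per worker (personal air monitor
plus end-of-shift urine).  Samples are dropped when urinary creatinine is
outside 0.3–3 g/L (over- or under-diluted urine) or when t,t-MA exceeds
1,000 μg/g Cr while air benzene is below 3 mg/m³ (a dietary sorbic-acid
signature, not benzene).  Air readings under the 0.05 mg/m³ detection limit
are not discarded: they are routed to the biomarker-only risk path.

Valid air samples are averaged into a worker-level C_TWA; cumulative
exposure Dc = C_TWA × T feeds the quartile-style grouping used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .risk import GROUP_BOUNDARIES, GROUP_LABELS, ExposureAssignment

__all__ = [
    "Sample",
    "WorkerRecord",
    "QcReport",
    "AIR_LOD_MG_M3",
    "qc_filter",
    "aggregate_worker",
    "assign_group",
    "assign_groups",
    "quartile_boundaries",
]

#: Limit of detection of the passive air monitors, mg/m³.
AIR_LOD_MG_M3 = 0.05

CREATININE_RANGE_G_L = (0.3, 3.0)
TTMA_SORBATE_CUTOFF = 1000.0  # μg/g Cr
TTMA_AIR_CUTOFF = 3.0  # mg/m³


@dataclass(frozen=True)
class Sample:
    """One monitoring round for one worker."""

    worker_id: str
    sample_round: int
    air_benzene: float  # mg/m³
    spma: float  # μg/g Cr
    ttma: float  # μg/g Cr
    creatinine: float | None  # g/L, None if the assay failed

    @property
    def below_lod(self) -> bool:
        return self.air_benzene < AIR_LOD_MG_M3


@dataclass(frozen=True)
class WorkerRecord:
    """One worker: monitoring samples plus duration and smoking status."""

    worker_id: str
    samples: tuple[Sample, ...]
    smoker: int
    duration: float  # working duration T, years

    def __post_init__(self) -> None:
        if not 1 <= len(self.samples) <= 3:
            raise ValueError("workers are monitored 1–3 times")
        if self.duration <= 0:
            raise ValueError("working duration must be positive")
        if self.smoker not in (0, 1):
            raise ValueError("smoker flag must be 0 or 1")


@dataclass
class QcReport:
    """Bookkeeping of sample-level QC; counters conserve the input size."""

    n_input: int = 0
    n_valid: int = 0
    n_excluded_creatinine: int = 0
    n_excluded_missing_creatinine: int = 0
    n_excluded_ttma_rule: int = 0
    n_below_lod: int = 0

    def check(self) -> None:
        total = (
            self.n_valid
            + self.n_excluded_creatinine
            + self.n_excluded_missing_creatinine
            + self.n_excluded_ttma_rule
            + self.n_below_lod
        )
        assert total == self.n_input, "QC counters do not conserve the input"

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def qc_filter(samples: Iterable[Sample]) -> tuple[list[Sample], list[Sample], QcReport]:
    """Apply the sample exclusion rules.

    Returns ``(valid, below_lod, report)``; below-LOD samples pass the urine
    checks but carry no usable air reading, so they are kept on a separate
    track for biomarker-only assessment rather than being discarded.
    """
    valid: list[Sample] = []
    below: list[Sample] = []
    report = QcReport()
    for s in samples:
        report.n_input += 1
        if s.creatinine is None:
            report.n_excluded_missing_creatinine += 1
            continue
        if not CREATININE_RANGE_G_L[0] <= s.creatinine <= CREATININE_RANGE_G_L[1]:
            report.n_excluded_creatinine += 1
            continue
        if s.air_benzene < TTMA_AIR_CUTOFF and s.ttma > TTMA_SORBATE_CUTOFF:
            report.n_excluded_ttma_rule += 1
            continue
        if s.below_lod:
            report.n_below_lod += 1
            below.append(s)
            continue
        report.n_valid += 1
        valid.append(s)
    report.check()
    return valid, below, report


def aggregate_worker(
    record: WorkerRecord, valid_samples: Sequence[Sample]
) -> ExposureAssignment | None:
    """Collapse a worker's valid air samples into an exposure assignment.

    C_TWA is the unweighted mean over valid rounds; Dc = C_TWA × T.  A
    worker with no valid air sample returns None (biomarker-only path).
    """
    own = [s for s in valid_samples if s.worker_id == record.worker_id]
    if not own:
        return None
    c_twa = float(np.mean([s.air_benzene for s in own]))
    return ExposureAssignment(
        worker_id=record.worker_id,
        c_twa=c_twa,
        duration=record.duration,
        smoker=record.smoker,
    )


def assign_group(
    dc: float, boundaries: Sequence[float] = GROUP_BOUNDARIES,
    labels: Sequence[str] = GROUP_LABELS,
) -> str:
    """Map a cumulative exposure to its half-open bin label.

    Bins are left-closed: [0, b1), [b1, b2), ..., [bk, inf).
    """
    if dc < 0:
        raise ValueError("cumulative exposure must be non-negative")
    if list(boundaries) != sorted(set(boundaries)):
        raise ValueError("boundaries must be strictly increasing")
    if len(labels) != len(boundaries) + 1:
        raise ValueError("need one more label than boundaries")
    idx = int(np.searchsorted(np.asarray(boundaries, dtype=float), dc, side="right"))
    return labels[idx]


def assign_groups(
    workers: Iterable[ExposureAssignment],
    boundaries: Sequence[float] = GROUP_BOUNDARIES,
    labels: Sequence[str] = GROUP_LABELS,
) -> list[ExposureAssignment]:
    """Return copies of the assignments with group labels filled in."""
    out = []
    for w in workers:
        out.append(
            ExposureAssignment(
                worker_id=w.worker_id, c_twa=w.c_twa, duration=w.duration,
                group_label=assign_group(w.dc, boundaries, labels), smoker=w.smoker,
            )
        )
    return out


def quartile_boundaries(dcs: Sequence[float]) -> tuple[float, ...]:
    """Data-driven alternative to the fixed {3, 5, 12} boundaries.

    Rounds the quartiles of the cumulative-exposure distribution to
    integers, dropping duplicates.
    """
    q = np.quantile(np.asarray(dcs, dtype=float), [0.25, 0.5, 0.75])
    rounded = sorted(set(int(round(v)) for v in q))
    return tuple(float(v) for v in rounded)
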