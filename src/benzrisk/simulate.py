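"""Synthetic cohort- and worker-level data with the study's structure.

No worker-level measurements are deposited with the study, so testing the
full pipeline requires data that look like it: four exposure groups of
23/24/26/25 workers, 2–3 monitoring rounds each (217 valid samples in
expectation), 23.5% smokers, log-normal airborne benzene matched to the
published group means/SDs on the arithmetic scale, and urinary metabolites
generated from the published log-log regressions with residual noise
calibrated so the refitted R² lands near the published 0.58 / 0.45.

All randomness flows from one seed through named substreams, so adding a
variable to the generator does not perturb the draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .biomarker import RegressionFit, SPMA_PUBLISHED, TTMA_PUBLISHED
from .exceptions import ConfigError
from .multistage import DoseGroup, MultistageResults
from .qc import AIR_LOD_MG_M3, Sample, WorkerRecord

__all__ = [
    "GroupSpec",
    "SyntheticConfig",
    "TABLE_GROUPS",
    "generate_cohort",
    "generate_workers",
    "workers_to_sample_frame",
    "write_samples_csv",
]


@dataclass(frozen=True)
class GroupSpec:
    """Exposure-group template: size, air moments, mean working duration."""

    label: str
    n: int
    air_mean: float  # mg/m³, arithmetic mean
    air_sd: float  # mg/m³, arithmetic SD
    duration_mean: float  # years


#: Default group structure of the exposed-worker study (per-group worker
#: counts, arithmetic air-benzene moments, mean working durations).
TABLE_GROUPS: tuple[GroupSpec, ...] = (
    GroupSpec("<3", 23, 2.31, 0.97, 0.76),
    GroupSpec("3–5", 24, 4.28, 2.05, 1.67),
    GroupSpec("5–12", 26, 5.31, 5.84, 2.41),
    GroupSpec("≥12", 25, 34.92, 60.37, 2.70),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the worker-level generator; defaults emulate the study."""

    seed: int = 0
    groups: tuple[GroupSpec, ...] = TABLE_GROUPS
    smoking_prevalence: float = 0.235
    spma_truth: RegressionFit = SPMA_PUBLISHED
    ttma_truth: RegressionFit = TTMA_PUBLISHED
    spma_target_r2: float = 0.58
    ttma_target_r2: float = 0.45
    creatinine_range: tuple[float, float] = (0.3, 3.0)
    creatinine_outlier_rate: float = 0.05
    sorbate_ttma_rate: float = 0.02  # low-air samples spiked above 1000 μg/g Cr
    below_lod_fraction: float = 5 / 103
    below_lod_air: float = 0.01  # mg/m³, latent exposure of below-LOD workers
    duration_cv: float = 0.5
    p_three_rounds: float = 0.215  # else two rounds; mean ≈ 2.21 rounds/worker
    worker_air_share: float = 0.7  # between-worker share of log-air variance

    def __post_init__(self) -> None:
        for name in ("smoking_prevalence", "creatinine_outlier_rate",
                     "sorbate_ttma_rate", "below_lod_fraction", "p_three_rounds",
                     "worker_air_share"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("spma_target_r2", "ttma_target_r2"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        if any(g.air_sd < 0 for g in self.groups):
            raise ConfigError("air SDs must be non-negative")
        if self.duration_cv < 0:
            raise ConfigError("duration CV must be non-negative")

    def scaled(self, factor: float) -> "SyntheticConfig":
        """Same structure with group sizes multiplied by ``factor``."""
        groups = tuple(
            replace(g, n=max(1, int(round(g.n * factor)))) for g in self.groups
        )
        return replace(self, groups=groups)


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named substream: independent generator keyed by (seed, name)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(int(seed), zlib.crc32(name.encode())))
    )


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with given arithmetic mean and SD."""
    if mean <= 0:
        raise ConfigError("log-normal mean must be positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2, np.sqrt(sigma2)


def generate_cohort(
    truth: MultistageResults,
    groups: Sequence[DoseGroup],
    seed: int,
) -> list[DoseGroup]:
    """Binomial cohort draw: cases ~ Bin(n_subjects, P(dose)) per stratum.

    ``groups`` supplies the dose midpoints and stratum sizes; the case
    counts are replaced by draws from the truth model.
    """
    rng = _rng(seed, "cohort_cases")
    out = []
    for g in groups:
        p = float(truth.predict(g.dose_midpoint))
        cases = int(rng.binomial(g.n_subjects, p)) if g.n_subjects > 0 else 0
        out.append(DoseGroup(g.dose_midpoint, g.n_subjects, cases))
    return out


def _calibrated_resid_sd(slope: float, var_ln_air: float, target_r2: float) -> float:
    """Residual SD giving the target R² at the realised ln-air variance.

    From R² = explained / total with explained ≈ b²·Var(lnC) (the small
    smoking term folded into the explained part):
    resid² = b²·Var(lnC)·(1−R²)/R².
    """
    return float(np.sqrt(slope**2 * var_ln_air * (1 - target_r2) / target_r2))


def generate_workers(config: SyntheticConfig) -> list[WorkerRecord]:
    """Draw a synthetic worker panel under ``config``.

    Deterministic given the config (seed included).  Group membership,
    monitoring rounds, smoking, durations, per-round air levels (log-normal,
    moment-matched per group, with a shared worker-level random effect),
    metabolites from the truth regressions plus calibrated noise, creatinine
    with a configurable invalid fraction, and a small contingent of workers
    whose true exposure sits below the air monitor's detection limit.
    """
    seed = config.seed
    n_exposed = sum(g.n for g in config.groups)
    f = config.below_lod_fraction
    n_below = int(round(f / (1 - f) * n_exposed)) if f < 1 else 0

    # -- structural draws ---------------------------------------------------
    rng_rounds = _rng(seed, "rounds")
    rng_smoke = _rng(seed, "smoking")
    rng_dur = _rng(seed, "duration")
    rng_air = _rng(seed, "air")
    rng_spma = _rng(seed, "spma_noise")
    rng_ttma = _rng(seed, "ttma_noise")
    rng_creat = _rng(seed, "creatinine")
    rng_sorb = _rng(seed, "sorbate")

    plan = []  # (worker_id, group, below_lod_flag)
    wid = 0
    for g in config.groups:
        for _ in range(g.n):
            plan.append((f"W{wid:04d}", g, False))
            wid += 1
    low_group = config.groups[0]
    for _ in range(n_below):
        plan.append((f"W{wid:04d}", low_group, True))
        wid += 1

    n_workers = len(plan)
    rounds = np.where(rng_rounds.random(n_workers) < config.p_three_rounds, 3, 2)
    smokers = (rng_smoke.random(n_workers) < config.smoking_prevalence).astype(int)

    # durations: log-normal around the group mean with the configured CV
    durations = np.empty(n_workers)
    for i, (_, g, _) in enumerate(plan):
        mu, sig = _lognormal_params(g.duration_mean, config.duration_cv * g.duration_mean)
        durations[i] = rng_dur.lognormal(mu, sig)

    # per-round air: worker effect + round noise on the log scale
    air: list[np.ndarray] = []
    for i, (_, g, below) in enumerate(plan):
        if below:
            smokers[i] = 0  # the study's below-LOD workers were all non-smokers
            mu, sig = _lognormal_params(config.below_lod_air, 0.3 * config.below_lod_air)
            vals = rng_air.lognormal(mu, sig, size=rounds[i])
            vals = np.minimum(vals, AIR_LOD_MG_M3 * 0.9)
        else:
            mu, sig = _lognormal_params(g.air_mean, g.air_sd)
            w_sd = sig * np.sqrt(config.worker_air_share)
            r_sd = sig * np.sqrt(1 - config.worker_air_share)
            worker_eff = rng_air.normal(0.0, w_sd)
            vals = np.exp(mu + worker_eff + rng_air.normal(0.0, r_sd, size=rounds[i]))
            vals = np.maximum(vals, AIR_LOD_MG_M3 * 1.01)
        air.append(vals)

    # residual SDs calibrated on the realised detectable ln-air variance
    ln_air_detectable = np.concatenate(
        [a for a, (_, _, below) in zip(air, plan) if not below]
    )
    var_ln = float(np.var(np.log(ln_air_detectable)))
    sd_spma = _calibrated_resid_sd(config.spma_truth.slope, var_ln, config.spma_target_r2)
    sd_ttma = _calibrated_resid_sd(config.ttma_truth.slope, var_ln, config.ttma_target_r2)

    lo_cr, hi_cr = config.creatinine_range
    workers: list[WorkerRecord] = []
    for i, (worker_id, g, below) in enumerate(plan):
        samples = []
        for j in range(rounds[i]):
            a = float(air[i][j])
            ln_spma = (
                config.spma_truth.slope * np.log(a)
                + config.spma_truth.smoking_coef * smokers[i]
                + config.spma_truth.intercept
                + rng_spma.normal(0.0, sd_spma)
            )
            ln_ttma = (
                config.ttma_truth.slope * np.log(a)
                + config.ttma_truth.smoking_coef * smokers[i]
                + config.ttma_truth.intercept
                + rng_ttma.normal(0.0, sd_ttma)
            )
            ttma = float(np.exp(ln_ttma))
            if not below and rng_sorb.random() < config.sorbate_ttma_rate:
                # dietary sorbic-acid artefact: implausibly high t,t-MA
                ttma = 1000.0 + rng_sorb.uniform(200.0, 3000.0)
            if rng_creat.random() < config.creatinine_outlier_rate:
                creat = float(
                    rng_creat.uniform(0.05, lo_cr)
                    if rng_creat.random() < 0.5
                    else rng_creat.uniform(hi_cr, hi_cr + 1.0)
                )
            else:
                creat = float(rng_creat.uniform(lo_cr, hi_cr))
            samples.append(
                Sample(
                    worker_id=worker_id, sample_round=j + 1, air_benzene=a,
                    spma=float(np.exp(ln_spma)), ttma=ttma, creatinine=creat,
                )
            )
        workers.append(
            WorkerRecord(
                worker_id=worker_id, samples=tuple(samples),
                smoker=int(smokers[i]), duration=float(durations[i]),
            )
        )
    return workers


def workers_to_sample_frame(workers: Sequence[WorkerRecord]) -> pd.DataFrame:
    """Long per-sample frame in the package's standard CSV schema."""
    rows = []
    for w in workers:
        for s in w.samples:
            rows.append(
                {
                    "worker_id": s.worker_id,
                    "sample_round": s.sample_round,
                    "air_benzene_mg_m3": s.air_benzene,
                    "spma_ug_gcr": s.spma,
                    "ttma_ug_gcr": s.ttma,
                    "creatinine_g_l": s.creatinine,
                    "smoker": w.smoker,
                    "duration_years": w.duration,
                }
            )
    return pd.DataFrame(rows)


def write_samples_csv(workers: Sequence[WorkerRecord], path) -> None:
    """Write the per-sample CSV with fixed float formatting (reproducible)."""
    workers_to_sample_frame(workers).to_csv(path, index=False, float_format="%.10g")
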