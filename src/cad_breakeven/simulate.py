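"""Synthetic reader-timing corpora and screening populations with known truth.

The corpus generator emulates the statistical structure behind a
multi-study reading-time evidence table: each study's true time saving
is drawn around a common mean with between-study heterogeneity tau, and
per-scan reading times add within-reader noise sigma.  Studies are then
summarised exactly the way published tables report them (per-reader mean
+/- SD per arm and a difference with a normal-theory CI), so the pooling
stage is format-agnostic about real versus simulated input.
"""

from __future__ import annotations

import math
from enum import Enum
from typing import Optional

import numpy as np
from pydantic import BaseModel, model_validator

from .corpus import (
    DispersionKind,
    Modality,
    ReadingMode,
    ReadingTimeObservation,
    TimeSummary,
)
from .pooling import Z_95


class Distribution(str, Enum):
    NORMAL = "normal"
    LOGNORMAL = "lognormal"


class SimulationSpec(BaseModel):
    """Ground-truth parameters for a simulated reading-time corpus.

    ``mu_no_cad_s`` and ``mu_saving_s`` are the population mean unaided
    reading time and mean time saved by CAD (seconds); ``tau`` is the
    between-study SD of the true saving and ``sigma`` the within-reader
    per-scan SD.  The lognormal option reproduces the right skew typical
    of reading times; its parameters are moment-matched so the stated
    means and SDs are preserved.
    """

    n_studies: int
    readers_per_study: int = 1
    scans_per_reader: int = 50
    mu_no_cad_s: float = 162.0
    mu_saving_s: float = 77.0
    tau_between_study_s: float = 25.0
    sigma_within_s: float = 40.0
    distribution: Distribution = Distribution.NORMAL
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationSpec":
        if min(self.n_studies, self.readers_per_study, self.scans_per_reader) < 1:
            raise ValueError("all counts must be >= 1")
        if self.tau_between_study_s < 0 or self.sigma_within_s < 0:
            raise ValueError("tau and sigma must be non-negative")
        if self.mu_no_cad_s <= 0:
            raise ValueError("mu_no_cad_s must be positive")
        return self


def _draw_times(rng: np.random.Generator, mean: float, sd: float, size: int,
                distribution: Distribution) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    if distribution == Distribution.NORMAL:
        return rng.normal(mean, sd, size)
    # lognormal with matched first two moments
    s2 = math.log1p((sd / mean) ** 2)
    mu_log = math.log(mean) - s2 / 2.0
    return rng.lognormal(mu_log, math.sqrt(s2), size)


def simulate_corpus(spec: SimulationSpec) -> list[ReadingTimeObservation]:
    """Generate a corpus of concurrent-reader observations, one per reader.

    Deterministic given ``spec.seed``.  Per study, the true saving is
    Normal(mu_saving, tau^2); per reader, scan times are drawn around the
    study means and summarised as mean +/- SD per arm.  The reported
    difference carries a normal-theory 95% CI so inverse-variance pooling
    has standard errors to work with.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[ReadingTimeObservation] = []
    n = spec.scans_per_reader
    # keep the with-CAD arm safely positive: reading a scan takes time, so
    # extreme heterogeneity draws are truncated a few sampling SEs above zero
    margin = max(1.0, 5.0 * spec.sigma_within_s / math.sqrt(n))
    for i in range(spec.n_studies):
        saving_i = rng.normal(spec.mu_saving_s, spec.tau_between_study_s) \
            if spec.tau_between_study_s > 0 else spec.mu_saving_s
        saving_i = min(saving_i, spec.mu_no_cad_s - margin)
        for r in range(spec.readers_per_study):
            t_no = _draw_times(rng, spec.mu_no_cad_s, spec.sigma_within_s, n, spec.distribution)
            t_with = _draw_times(
                rng, spec.mu_no_cad_s - saving_i, spec.sigma_within_s, n, spec.distribution
            )
            mean_no, sd_no = float(t_no.mean()), float(t_no.std(ddof=1)) if n > 1 else 0.0
            mean_with, sd_with = float(t_with.mean()), float(t_with.std(ddof=1)) if n > 1 else 0.0
            diff = mean_with - mean_no
            if diff >= 0:
                # heavy noise can flip a study's sign; clamp just below zero so
                # the concurrent-reader sign invariant holds
                diff = -1e-9
            se = math.sqrt((sd_no**2 + sd_with**2) / n)
            out.append(
                ReadingTimeObservation(
                    study_label=f"Sim study {i + 1}",
                    country="simulated",
                    modality=Modality.LOW_DOSE_CT,
                    cad_product="simulated DL-CAD",
                    reading_mode=ReadingMode.CONCURRENT_READER,
                    reader_label=f"Reader {r + 1}" if spec.readers_per_study > 1 else "",
                    time_no_cad=_summary(mean_no, sd_no),
                    time_with_cad=_summary(mean_with, sd_with),
                    reported_difference_seconds=diff,
                    reported_difference_ci=(diff - Z_95 * se, diff + Z_95 * se) if se > 0 else None,
                    p_value_text=None,
                )
            )
    return out


def _summary(mean: float, sd: float) -> TimeSummary:
    if sd > 0:
        return TimeSummary(central=mean, dispersion=sd, dispersion_kind=DispersionKind.SD)
    return TimeSummary(central=mean, dispersion_kind=DispersionKind.NONE)


def simulate_screening_population(
    n_scans: int,
    prevalence: float,
    ruleout_sensitivity_for_negatives: float,
    seed: int = 0,
) -> tuple[int, int]:
    """Simulate pre-screening triage of a screening population.

    Nodule-positive scans are never ruled out; each nodule-free scan is
    ruled out independently with the stated probability.  Returns
    ``(n_ruled_out, n_read_by_radiologist)``, summing to ``n_scans``.
    """
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    if not 0 <= prevalence <= 1 or not 0 <= ruleout_sensitivity_for_negatives <= 1:
        raise ValueError("proportions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_positive = int(rng.binomial(n_scans, prevalence))
    n_negative = n_scans - n_positive
    n_ruled_out = int(rng.binomial(n_negative, ruleout_sensitivity_for_negatives))
    return n_ruled_out, n_scans - n_ruled_out
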