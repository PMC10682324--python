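"""Random-effects pooling of reading times across studies.

Two pooling routes are provided.  The default is an unweighted mean of
the study-level estimates with a t-based 95% CI, because several
published arms report no dispersion at all, which rules out a complete
inverse-variance pool.  When every study supplies (or is imputed) a
standard error, the moment-based DerSimonian-Laird random-effects
estimator is available:

    Q    = sum w_i (y_i - ybar_FE)^2,          w_i = 1/se_i^2
    tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))
    w*_i = 1/(se_i^2 + tau2)
    mean = sum w* y / sum w*,   CI = mean +/- 1.96 / sqrt(sum w*)

Median (IQR) summaries are converted to mean/SD with the Wan
quantile estimator before pooling.
"""

from __future__ import annotations

import math
import warnings
from enum import Enum
from statistics import mean as _amean
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, model_validator
from scipy import stats

from .corpus import DispersionKind, ReadingMode, ReadingTimeObservation

Z_95 = 1.959964  # two-sided 95% normal quantile


class PoolingMethod(str, Enum):
    DERSIMONIAN_LAIRD = "dersimonian_laird"
    UNWEIGHTED = "unweighted"
    FIXED_EFFECT = "fixed_effect"


class Arm(str, Enum):
    NO_CAD = "no_cad"
    WITH_CAD_CONCURRENT = "with_cad_concurrent"
    SAVED_TIME_CONCURRENT = "saved_time_concurrent"


class MultiReaderPolicy(str, Enum):
    AVERAGE_WITHIN_STUDY = "average_within_study"
    TREAT_AS_INDEPENDENT = "treat_as_independent"


class EffectInput(BaseModel):
    """One study-level estimate entering a pool."""

    study_label: str
    estimate: float
    se: Optional[float] = None
    n_info: Optional[int] = None

    @model_validator(mode="after")
    def _check(self) -> "EffectInput":
        if self.se is not None and self.se <= 0:
            raise ValueError(f"{self.study_label}: se must be positive, got {self.se}")
        return self


class PooledEstimate(BaseModel):
    """Pooled mean with 95% CI and heterogeneity statistics."""

    mean: float
    ci_lo: float
    ci_hi: float
    k_studies: int
    tau2: Optional[float] = None
    q_stat: Optional[float] = None
    method: PoolingMethod

    @model_validator(mode="after")
    def _check(self) -> "PooledEstimate":
        if not self.ci_lo <= self.mean <= self.ci_hi:
            raise ValueError(f"CI ({self.ci_lo}, {self.ci_hi}) must bracket mean {self.mean}")
        if self.k_studies < 1:
            raise ValueError("k_studies must be >= 1")
        if self.tau2 is not None and self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        return self


def median_iqr_to_mean_sd(
    median: float, q1: float, q3: float, n: Optional[int] = None
) -> tuple[float, float]:
    """Estimate mean and SD from a median and quartiles (Wan estimator).

    mean = (q1 + median + q3) / 3.  SD uses the large-sample quartile
    denominator (q3 - q1)/1.35 when ``n`` is unknown, or the n-dependent
    denominator 2 * Phi^-1((0.75 n - 0.125)/(n + 0.25)) when given.
    """
    if q1 > q3:
        raise ValueError(f"q1 ({q1}) must not exceed q3 ({q3})")
    if not q1 <= median <= q3:
        raise ValueError(f"median {median} must lie within [{q1}, {q3}]")
    mean = (q1 + median + q3) / 3.0
    if q1 == q3:
        warnings.warn("degenerate IQR (q1 == q3): SD estimated as 0", stacklevel=2)
        return mean, 0.0
    if n is None:
        denom = 1.35
    else:
        denom = 2.0 * stats.norm.ppf((0.75 * n - 0.125) / (n + 0.25))
    return mean, (q3 - q1) / denom


def ci_to_se(ci_lo: float, ci_hi: float, level: float = 0.95) -> float:
    """Back out a standard error from a symmetric normal confidence interval."""
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    if ci_lo > ci_hi:
        raise ValueError(f"ci_lo ({ci_lo}) must not exceed ci_hi ({ci_hi})")
    if ci_lo == ci_hi:
        warnings.warn("zero-width CI: se = 0", stacklevel=2)
        return 0.0
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (ci_hi - ci_lo) / (2.0 * z)


def pool_random_effects(
    effects: Sequence[EffectInput],
    method: PoolingMethod | str = PoolingMethod.UNWEIGHTED,
) -> PooledEstimate:
    """Pool study-level estimates into a mean with a 95% CI.

    ``dersimonian_laird`` and ``fixed_effect`` require a standard error on
    every effect; ``unweighted`` ignores standard errors and uses the
    t-distribution on the k study estimates.
    """
    method = PoolingMethod(method)
    if not effects:
        raise ValueError("cannot pool an empty list of effects")
    y = np.array([e.estimate for e in effects], dtype=float)
    k = len(y)

    if method == PoolingMethod.UNWEIGHTED:
        m = float(y.mean())
        if k == 1:
            e = effects[0]
            half = Z_95 * e.se if e.se is not None else 0.0
            if e.se is None:
                warnings.warn("single study without se: CI collapses to the point", stacklevel=2)
            return PooledEstimate(
                mean=m, ci_lo=m - half, ci_hi=m + half, k_studies=1, method=method
            )
        sd = float(y.std(ddof=1))
        half = stats.t.ppf(0.975, k - 1) * sd / math.sqrt(k)
        return PooledEstimate(mean=m, ci_lo=m - half, ci_hi=m + half, k_studies=k, method=method)

    missing = [e.study_label for e in effects if e.se is None]
    if missing:
        raise ValueError(
            f"{method.value} pooling needs a standard error for every study; "
            f"missing for {missing}; use method='unweighted' instead"
        )
    se = np.array([e.se for e in effects], dtype=float)
    w = 1.0 / se**2
    y_fe = float((w * y).sum() / w.sum())
    q = float((w * (y - y_fe) ** 2).sum())

    if method == PoolingMethod.FIXED_EFFECT or k == 1:
        tau2 = 0.0
    else:
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (q - (k - 1)) / denom)
        # DL reduces to the fixed-effect pool when tau2 clamps to zero
    if method == PoolingMethod.FIXED_EFFECT:
        w_star = w
    else:
        w_star = 1.0 / (se**2 + tau2)
    m = float((w_star * y).sum() / w_star.sum())
    half = Z_95 / math.sqrt(w_star.sum())
    return PooledEstimate(
        mean=m,
        ci_lo=m - half,
        ci_hi=m + half,
        k_studies=k,
        tau2=tau2,
        q_stat=q if k > 1 else None,
        method=method,
    )


def _study_arm_effect(obs: ReadingTimeObservation, arm: Arm) -> tuple[float, Optional[float]]:
    """Per-observation (estimate, se) for one pooling arm, in seconds."""
    if arm == Arm.SAVED_TIME_CONCURRENT:
        est = -obs.difference_seconds  # saved time as a positive magnitude
        if obs.reported_difference_ci is not None:
            se = ci_to_se(*obs.reported_difference_ci)
            return est, (se if se > 0 else None)
        return est, None
    ts = obs.time_no_cad if arm == Arm.NO_CAD else obs.time_with_cad
    if ts.dispersion_kind == DispersionKind.IQR_BOUNDS:
        mean, _sd = median_iqr_to_mean_sd(ts.central, *ts.bounds)
        return mean, None  # per-scan SD is not a study-level SE without n
    if ts.dispersion_kind == DispersionKind.CI_BOUNDS:
        return ts.central, ci_to_se(*ts.bounds) or None
    return ts.central, None


def extract_effects(
    corpus: Sequence[ReadingTimeObservation],
    arm: Arm | str,
    multi_reader_policy: MultiReaderPolicy | str = MultiReaderPolicy.AVERAGE_WITHIN_STUDY,
) -> list[EffectInput]:
    """Study-level effects for one arm over the concurrent-reader stratum.

    Median (IQR) arms are converted with the Wan estimator; reported
    difference CIs provide standard errors where available; multi-reader
    rows are averaged within study by default so each cohort enters once.
    """
    arm = Arm(arm)
    policy = MultiReaderPolicy(multi_reader_policy)
    rows = [o for o in corpus if o.reading_mode == ReadingMode.CONCURRENT_READER]
    if not rows:
        raise ValueError(f"no concurrent-reader observations available for arm {arm.value!r}")

    per_obs = [(o.study_label, *_study_arm_effect(o, arm)) for o in rows]
    if policy == MultiReaderPolicy.TREAT_AS_INDEPENDENT:
        return [
            EffectInput(study_label=lbl, estimate=est, se=se) for lbl, est, se in per_obs
        ]
    by_study: dict[str, list[tuple[float, Optional[float]]]] = {}
    for lbl, est, se in per_obs:
        by_study.setdefault(lbl, []).append((est, se))
    effects = []
    for lbl, vals in by_study.items():
        est = _amean(v[0] for v in vals)
        ses = [v[1] for v in vals]
        if all(s is not None for s in ses):
            # mean of readers: se of the average assuming independence
            se = math.sqrt(sum(s**2 for s in ses)) / len(ses)
        else:
            se = None
        effects.append(EffectInput(study_label=lbl, estimate=est, se=se))
    return effects


def pool_reading_times(
    corpus: Sequence[ReadingTimeObservation],
    arm: Arm | str,
    method: PoolingMethod | str = PoolingMethod.UNWEIGHTED,
    multi_reader_policy: MultiReaderPolicy | str = MultiReaderPolicy.AVERAGE_WITHIN_STUDY,
) -> PooledEstimate:
    """Pool one reading-time arm of the corpus across studies.

    ``saved_time_concurrent`` pools the per-study time saved by concurrent
    CAD reading (positive seconds); ``no_cad``/``with_cad_concurrent`` pool
    the arm means of the concurrent-reader studies.
    """
    effects = extract_effects(corpus, arm, multi_reader_policy)
    return pool_random_effects(effects, method)


def summarize_second_reader(
    corpus: Sequence[ReadingTimeObservation],
) -> tuple[float, float]:
    """(min, max) reading-time increase across second-reader studies, seconds."""
    diffs = [
        o.difference_seconds
        for o in corpus
        if o.reading_mode == ReadingMode.SECOND_READER
    ]
    if not diffs:
        raise ValueError("no second-reader observations in corpus")
    return min(diffs), max(diffs)
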