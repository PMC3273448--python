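"""Classical small-area variation analysis (SAVA).

Per-area indirect utilization ratios (IUR = o/e, the utilization analogue of
a standardized incidence ratio) with exact Poisson intervals, and the usual
statistics of between-area variation: the extremal quotient (EQ), the plain
and population-weighted coefficients of variation (CV, CVw), the systematic
component of variation (SCV) and a moment-based empirical-Bayes estimate of
the between-area variance of relative risks (EB).

These statistics treat areas as independent; the spatial models in
:mod:`arealvar.bym` and :mod:`arealvar.scm` relax that assumption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .areal_data import ArealCounts

__all__ = [
    "UtilizationRatios",
    "VariationStatistics",
    "indirect_utilization_ratio",
    "extremal_quotient",
    "coefficient_of_variation",
    "systematic_component_of_variation",
    "empirical_bayes_statistic",
    "variation_statistics",
]


@dataclass(frozen=True)
class UtilizationRatios:
    area_ids: tuple
    iur: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    level: float

    @property
    def significant_high(self) -> np.ndarray:
        return self.ci_low > 1.0

    @property
    def significant_low(self) -> np.ndarray:
        return self.ci_high < 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "area_id": self.area_ids,
                "iur": self.iur,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "significant_high": self.significant_high,
                "significant_low": self.significant_low,
            }
        )


def indirect_utilization_ratio(counts: ArealCounts, level: float = 0.95) -> UtilizationRatios:
    """Per-area o/e ratio with an exact (Poisson-gamma) interval.

    The ``level`` interval for the Poisson mean given an observation ``o`` is
    ``[Gamma(o, 1) quantile at (1-level)/2, Gamma(o+1, 1) quantile at
    1-(1-level)/2]``; dividing by ``e`` gives the interval for the ratio.
    The lower bound is 0 when ``o = 0``.
    """
    if counts.expected is None:
        counts = counts.with_expected()
    e = np.asarray(counts.expected, dtype=float)
    if np.any(e <= 0):
        raise ValueError("expected counts must be strictly positive")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    o = counts.observed.astype(float)
    a = (1 - level) / 2
    lo = np.where(o > 0, stats.gamma.ppf(a, np.maximum(o, 1e-12)), 0.0) / e
    hi = stats.gamma.ppf(1 - a, o + 1) / e
    return UtilizationRatios(counts.area_ids, o / e, lo, hi, level)


def extremal_quotient(rates, lo: float = 5, hi: float = 95) -> float:
    """Ratio of the ``hi``-th to the ``lo``-th percentile of per-area rates.

    Percentiles use linear interpolation between order statistics.
    """
    r = np.asarray(rates, dtype=float)
    if np.any(r <= 0):
        raise ValueError("all rates must be strictly positive")
    p_lo, p_hi = np.percentile(r, [lo, hi])
    return float(p_hi / p_lo)


def coefficient_of_variation(rates, weights=None) -> float:
    """Unweighted (sample sd / mean) or population-weighted CV of area rates."""
    r = np.asarray(rates, dtype=float)
    if r.size == 0:
        raise ValueError("rates must be non-empty")
    if weights is None:
        m = r.mean()
        if m <= 0:
            raise ValueError("mean rate must be positive")
        return float(r.std(ddof=1) / m)
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0) or w.size != r.size:
        raise ValueError("weights must be positive and aligned with rates")
    w = w / w.sum()
    m = float(w @ r)
    if m <= 0:
        raise ValueError("weighted mean rate must be positive")
    sd = float(np.sqrt(w @ (r - m) ** 2))
    return sd / m


def systematic_component_of_variation(counts: ArealCounts) -> float:
    """SCV: noise-corrected between-area variation of o/e ratios.

    ``SCV = (1/n) * sum_i [ ((o_i - e_i)/e_i)^2 - 1/e_i ]`` on the natural
    scale.  The ``1/e_i`` term removes the Poisson sampling contribution, so
    SCV can be (slightly) negative when observed variation is at chance level.
    """
    e = _expected(counts)
    o = counts.observed.astype(float)
    return float(np.mean(((o - e) / e) ** 2 - 1.0 / e))


def empirical_bayes_statistic(counts: ArealCounts) -> float:
    """Moment estimate of the between-area variance of relative risks.

    Marshall-type estimator: with ``r_i = o_i/e_i`` and the pooled ratio
    ``rbar = sum(o)/sum(e)``,

    ``EB = max(0, sum_i e_i (r_i - rbar)^2 / sum(e)  -  rbar * n / sum(e))``.

    The second term is the expected contribution of Poisson noise.
    """
    e = _expected(counts)
    o = counts.observed.astype(float)
    n = e.size
    rbar = o.sum() / e.sum()
    r = o / e
    v = float((e * (r - rbar) ** 2).sum() / e.sum()) - rbar * n / e.sum()
    return max(0.0, v)


def _expected(counts: ArealCounts) -> np.ndarray:
    if counts.expected is None:
        counts = counts.with_expected()
    e = np.asarray(counts.expected, dtype=float)
    if np.any(e <= 0):
        raise ValueError("expected counts must be strictly positive")
    return e


@dataclass(frozen=True)
class VariationStatistics:
    """Point estimates and bootstrap percentile intervals for the five statistics."""

    estimates: dict[str, float]
    ci_low: dict[str, float] | None
    ci_high: dict[str, float] | None
    level: float
    n_boot: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, v in self.estimates.items():
            row = {"statistic": k, "estimate": v}
            if self.ci_low is not None:
                row["ci_low"] = self.ci_low.get(k, np.nan)
                row["ci_high"] = self.ci_high.get(k, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)


def _all_statistics(counts: ArealCounts) -> dict[str, float]:
    rates = counts.rates
    return {
        "eq": extremal_quotient(rates) if np.all(rates > 0) else np.nan,
        "cv": coefficient_of_variation(rates),
        "cvw": coefficient_of_variation(rates, counts.population),
        "scv": systematic_component_of_variation(counts),
        "eb": empirical_bayes_statistic(counts),
    }


def variation_statistics(
    counts: ArealCounts,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> VariationStatistics:
    """All five variation statistics with parametric-bootstrap intervals.

    Each bootstrap replicate redraws ``o_i* ~ Poisson(e_i * r_i)`` (the
    fitted saturated-model mean, i.e. ``o_i``), recomputes every statistic
    and takes the percentile interval.  ``n_boot = 0`` returns point
    estimates only.
    """
    if counts.n_areas < 2:
        raise ValueError("need at least two areas")
    if counts.expected is None:
        counts = counts.with_expected()
    est = _all_statistics(counts)
    if n_boot == 0:
        return VariationStatistics(est, None, None, level, 0)
    rng = np.random.default_rng(seed)
    mu = counts.observed.astype(float)  # e_i * (o_i/e_i)
    reps: dict[str, list[float]] = {k: [] for k in est}
    for _ in range(n_boot):
        o_star = rng.poisson(mu)
        try:
            c_star = ArealCounts(counts.area_ids, o_star, counts.population, counts.expected)
            s = _all_statistics(c_star)
        except ValueError:
            continue
        for k in reps:
            reps[k].append(s[k])
    a = (1 - level) / 2 * 100
    # percentile intervals, expanded to contain the point estimate (relevant
    # for boundary statistics: EQ* >= 1 strictly under resampling noise even
    # when the observed EQ is exactly 1)
    lo = {k: float(min(np.nanpercentile(v, a), est[k])) for k, v in reps.items()}
    hi = {k: float(max(np.nanpercentile(v, 100 - a), est[k])) for k, v in reps.items()}
    return VariationStatistics(est, lo, hi, level, n_boot)
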