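"""Survival analyses for the adjudicated cohort.

Kaplan-Meier medians with confidence intervals, the log-rank test of
overall survival between progressors and non-progressors, paired
Wilcoxon signed-rank comparison of progression-free survival across
criteria systems with Bonferroni correction (three pairwise tests, so
p < 0.017 is significant), the Spearman correlation between OS and
PFS, and single-covariate Cox proportional-hazards regression of OS on
the diameter- and volume-change endpoints.

Kaplan-Meier and Cox fitting are delegated to lifelines; Cox uses the
Efron approximation for tied event times.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import median_survival_times
from scipy import stats as sps

__all__ = [
    "KMEstimate",
    "SurvivalFit",
    "km_fit",
    "logrank_pd_vs_nonpd",
    "paired_pfs_comparison",
    "spearman_os_pfs",
    "cox_univariate",
    "BONFERRONI_ALPHA",
]

#: Significance level for the three pairwise PFS comparisons (0.05 / 3).
BONFERRONI_ALPHA = 0.017


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival estimate.

    ``median`` is the smallest time with S(t) <= 0.5 (``None`` when the
    curve never reaches 0.5); the CI bounds are Brookmeyer-Crowley
    style as produced by lifelines.
    """

    times: np.ndarray
    survival: np.ndarray
    median: float | None
    median_ci: tuple[float | None, float | None]
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


@dataclass(frozen=True)
class SurvivalFit:
    """Single-covariate Cox proportional-hazards fit.

    The hazard ratio is per one ``covariate_unit`` increase of the
    covariate (e.g. per 10,000 mm^3 of volume change); CI bounds are
    Wald 95% limits.
    """

    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    log_partial_likelihood: float
    covariate_unit: str
    n: int
    n_events: int


def _finite_or_none(x: float) -> float | None:
    return None if x is None or not np.isfinite(x) else float(x)


def km_fit(times: Sequence[float], events: Sequence[bool]) -> KMEstimate:
    """Kaplan-Meier product-limit estimate with median and 95% CI."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if np.any(times < 0):
        raise ValueError("survival times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    median = _finite_or_none(kmf.median_survival_time_)
    if events.sum() == 0:
        median = None
        ci = (None, None)
    else:
        ci_df = median_survival_times(kmf.confidence_interval_)
        lo, hi = float(ci_df.iloc[0, 0]), float(ci_df.iloc[0, 1])
        ci = (_finite_or_none(lo), _finite_or_none(hi))
    return KMEstimate(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        median=median,
        median_ci=ci,
        n=len(times),
        n_events=int(events.sum()),
    )


def logrank_pd_vs_nonpd(
    os_times: Sequence[float],
    os_events: Sequence[bool],
    is_pd: Sequence[bool],
    criteria: str = "",
) -> float:
    """Log-rank p-value for OS of progressors vs non-progressors."""
    os_times = np.asarray(os_times, dtype=float)
    os_events = np.asarray(os_events, dtype=bool)
    is_pd = np.asarray(is_pd, dtype=bool)
    if is_pd.all() or (~is_pd).all():
        raise ValueError(
            f"log-rank needs both PD and non-PD patients"
            + (f" under {criteria}" if criteria else "")
        )
    res = logrank_test(
        os_times[is_pd], os_times[~is_pd], os_events[is_pd], os_events[~is_pd]
    )
    return float(res.p_value)


def _signed_rank(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p; zero differences dropped.

    Exact null distribution when <= 25 nonzero pairs (no ties in the
    absolute differences), otherwise the normal approximation with
    continuity correction.
    """
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    use_exact = d.size <= 25 and np.unique(np.abs(d)).size == d.size
    res = sps.wilcoxon(
        d, zero_method="wilcox", correction=True, method="exact" if use_exact else "approx"
    )
    return float(res.pvalue)


def paired_pfs_comparison(
    pfs_by_criteria: dict[str, Sequence[float]],
    alpha: float = BONFERRONI_ALPHA,
) -> pd.DataFrame:
    """Pairwise Wilcoxon signed-rank comparison of per-patient PFS.

    Returns one row per criteria pair with the two-sided p-value and a
    Bonferroni significance flag at ``alpha``.
    """
    names = list(pfs_by_criteria)
    vectors = {k: np.asarray(v, dtype=float) for k, v in pfs_by_criteria.items()}
    lengths = {v.size for v in vectors.values()}
    if len(lengths) != 1:
        raise ValueError("PFS vectors must be paired (equal length)")
    rows = []
    for a, b in combinations(names, 2):
        p = _signed_rank(vectors[a], vectors[b])
        rows.append(
            {"criteria_a": a, "criteria_b": b, "p_value": p, "significant": p < alpha}
        )
    return pd.DataFrame(rows)


def spearman_os_pfs(
    os_values: Sequence[float], pfs_values: Sequence[float]
) -> tuple[float, tuple[float, float], float]:
    """Spearman rank correlation of OS with PFS, with Fisher 95% CI.

    Ties are mid-ranked.  Returns ``(rho, (ci_low, ci_high), p)``;
    raises on a constant vector (correlation undefined).
    """
    x = np.asarray(os_values, dtype=float)
    y = np.asarray(pfs_values, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 paired observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(x.size - 3)
    lo, hi = np.tanh(z - 1.959963984540054 * se), np.tanh(z + 1.959963984540054 * se)
    return float(rho), (float(lo), float(hi)), float(p)


def cox_univariate(
    os_months: Sequence[float],
    os_event: Sequence[bool],
    covariate: Sequence[float],
    unit_scale: float = 1.0,
    covariate_unit: str = "1 unit",
) -> SurvivalFit:
    """Cox proportional-hazards regression of OS on a single covariate.

    The covariate is divided by ``unit_scale`` before fitting so the
    hazard ratio is per ``unit_scale`` raw units (10,000 mm^3 for the
    volume-change endpoint, 1 mm for diameter change).  Ties are
    handled with the Efron approximation; the CI and p-value are Wald.
    """
    t = np.asarray(os_months, dtype=float)
    e = np.asarray(os_event, dtype=bool)
    x = np.asarray(covariate, dtype=float) / unit_scale
    if e.sum() < 1:
        raise ValueError("Cox regression needs at least one event")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate: hazard ratio not identifiable")
    df = pd.DataFrame({"time": t, "event": e.astype(int), "x": x})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    summ = cph.summary.loc["x"]
    return SurvivalFit(
        hazard_ratio=float(summ["exp(coef)"]),
        ci_low=float(summ["exp(coef) lower 95%"]),
        ci_high=float(summ["exp(coef) upper 95%"]),
        p_value=float(summ["p"]),
        log_partial_likelihood=float(cph.log_likelihood_),
        covariate_unit=covariate_unit,
        n=len(df),
        n_events=int(e.sum()),
    )
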