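"""Inter-criteria comparison statistics.

Covers the agreement battery used to compare response adjudications
from two criteria systems on the same patients: best-response rate
tables (ORR, DCR), quadratically weighted kappa on the ordered
CR < PR < SD < PD scale, the exact McNemar test on paired progression
assignments, and the power of the paired z-test used for the
progression-free-survival comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .criteria import Category

__all__ = [
    "CATEGORY_ORDER",
    "AgreementResult",
    "response_rate_table",
    "weighted_kappa",
    "kappa_band",
    "mcnemar_exact",
    "paired_z_power",
]

#: Ordered response scale used for weighting.
CATEGORY_ORDER = [Category.CR, Category.PR, Category.SD, Category.PD]
_INDEX = {c: i for i, c in enumerate(CATEGORY_ORDER)}


@dataclass(frozen=True)
class AgreementResult:
    """Weighted-kappa agreement between two raters/criteria.

    ``confusion_matrix`` holds counts over CR/PR/SD/PD (rows = first
    rater).  ``weight_matrix`` holds the quadratic *agreement* weights
    ``w_ij = 1 - (i - j)^2 / (k - 1)^2``; the kappa itself is computed
    from the complementary disagreement weights ``v = 1 - w`` (the
    convention is recorded here explicitly to avoid the classic
    ambiguity).  ``band`` is the qualitative agreement label.
    """

    confusion_matrix: np.ndarray
    kappa: float | None
    weight_matrix: np.ndarray
    band: str | None
    n: int
    weight_convention: str = "agreement weights w_ij = 1 - (i-j)^2/(k-1)^2"


def kappa_band(kappa: float) -> str:
    """Qualitative agreement band for a kappa value."""
    if kappa <= 0.20:
        return "poor"
    if kappa <= 0.40:
        return "mild"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"


def _as_category(x) -> Category:
    return x if isinstance(x, Category) else Category(str(x))


def response_rate_table(
    categories_by_criteria: dict[str, Sequence[Category | str]],
) -> pd.DataFrame:
    """Best-response counts and percentages per criteria system.

    Returns a frame indexed by criteria name with count and percent
    columns for CR/PR/SD/PD plus the overall response rate
    (ORR = CR + PR) and disease control rate (DCR = CR + PR + SD).
    Percentages are rounded to one decimal.
    """
    rows = {}
    for name, cats in categories_by_criteria.items():
        cats = [_as_category(c) for c in cats]
        bad = [c for c in cats if c not in _INDEX]
        if bad:
            raise ValueError(f"{name}: categories outside CR/PR/SD/PD: {bad}")
        n = len(cats)
        counts = {c.value: sum(cat is c for cat in cats) for c in CATEGORY_ORDER}
        row = {"n": n}
        for c in CATEGORY_ORDER:
            row[f"{c.value}_count"] = counts[c.value]
            row[f"{c.value}_pct"] = round(100.0 * counts[c.value] / n, 1)
        orr = counts["CR"] + counts["PR"]
        dcr = orr + counts["SD"]
        row["ORR_count"], row["ORR_pct"] = orr, round(100.0 * orr / n, 1)
        row["DCR_count"], row["DCR_pct"] = dcr, round(100.0 * dcr / n, 1)
        rows[name] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def weighted_kappa(
    ratings_a: Sequence[Category | str], ratings_b: Sequence[Category | str]
) -> AgreementResult:
    """Quadratically weighted kappa for paired ordinal ratings.

    With observed cell proportions ``O`` and chance-expected
    proportions ``E`` (products of the marginals) over the k = 4
    ordered categories,

        kappa = 1 - sum(v_ij O_ij) / sum(v_ij E_ij),

    where ``v_ij = (i - j)^2 / (k - 1)^2`` are the quadratic
    disagreement weights.  Kappa is undefined (``None``) when fewer
    than two distinct categories occur across both raters.
    """
    a = [_as_category(c) for c in ratings_a]
    b = [_as_category(c) for c in ratings_b]
    if len(a) != len(b):
        raise ValueError("ratings must be paired")
    k = len(CATEGORY_ORDER)
    conf = np.zeros((k, k))
    for ca, cb in zip(a, b):
        conf[_INDEX[ca], _INDEX[cb]] += 1
    n = int(conf.sum())
    idx = np.arange(k)
    v = (idx[:, None] - idx[None, :]) ** 2 / (k - 1) ** 2
    w = 1.0 - v
    if len({*a, *b}) < 2:
        return AgreementResult(conf, None, w, None, n)
    obs = conf / n
    expected = np.outer(conf.sum(axis=1), conf.sum(axis=0)) / n**2
    denom = float((v * expected).sum())
    if denom == 0.0:  # degenerate marginals (perfect agreement on one class each)
        kappa = 1.0
    else:
        kappa = 1.0 - float((v * obs).sum()) / denom
    return AgreementResult(conf, kappa, w, kappa_band(kappa), n)


def mcnemar_exact(
    pd_a: Sequence[bool], pd_b: Sequence[bool]
) -> tuple[float, tuple[int, int]]:
    """Exact McNemar test on paired progression assignments.

    Compares the proportion of patients called progressive disease by
    two criteria using the exact binomial test on the discordant pairs
    ``b`` (PD by A only) and ``c`` (PD by B only):

        p = min(1, 2 * P(X <= min(b, c))),  X ~ Binomial(b + c, 1/2).

    Returns ``(p_value, (b, c))``; ``p = 1`` when there are no
    discordant pairs.
    """
    a = np.asarray(pd_a, dtype=bool)
    bb = np.asarray(pd_b, dtype=bool)
    if a.shape != bb.shape:
        raise ValueError("paired vectors must have equal length")
    b = int(np.sum(a & ~bb))
    c = int(np.sum(~a & bb))
    if b + c == 0:
        return 1.0, (b, c)
    p = sps.binomtest(min(b, c), n=b + c, p=0.5, alternative="two-sided").pvalue
    return float(min(1.0, p)), (b, c)


def paired_z_power(
    n: int, mean_diff: float, sd_diff: float, alpha: float = 0.05
) -> float:
    """Power of the two-sided paired z-test.

    For ``n`` pairs with true mean paired difference ``mean_diff`` and
    standard deviation of the differences ``sd_diff``,

        power = Phi(delta - z_{1-alpha/2}) + Phi(-delta - z_{1-alpha/2}),

    with noncentrality ``delta = sqrt(n) |mean_diff| / sd_diff``; the
    second term is the (usually negligible) opposite tail.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if sd_diff <= 0:
        raise ValueError("sd_diff must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    z = sps.norm.ppf(1 - alpha / 2)
    delta = np.sqrt(n) * abs(mean_diff) / sd_diff
    return float(sps.norm.cdf(delta - z) + sps.norm.cdf(-delta - z))
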