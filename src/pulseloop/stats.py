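"""Statistical helpers used across the analysis stack.

Paired t-tests with Cohen's d, post hoc power for the paired two-tailed
t-test via the noncentral t-distribution, Pearson correlation with a
Fisher-z confidence interval, Spearman rank correlation, Cohen's kappa for
rater agreement, Benjamini-Hochberg FDR correction, and the angular
subtense of a target (visual-angle equivalence of scaled shooting
distances).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


def paired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Classic paired t-test on the differences; returns (t, df, two-tailed p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, n - 1, 1.0
        raise ValueError("zero-variance nonzero differences: t undefined")
    t = d.mean() / (sd / math.sqrt(n))
    p = 2 * sps.t.sf(abs(t), df=n - 1)
    return float(t), n - 1, float(p)


def cohen_d_paired(x: Sequence[float], y: Sequence[float]) -> float:
    """Paired effect size d = mean(diff) / SD(diff) (n-1 denominator)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    d = x - y
    if d.size < 2:
        raise ValueError("need at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return 0.0
        raise ValueError("constant nonzero differences: d undefined")
    return float(d.mean() / sd)


@dataclass(frozen=True)
class PowerQuery:
    d: float
    n: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def power_paired_t(q: PowerQuery) -> float:
    """Power of a two-tailed paired t-test, noncentral-t method.

    Noncentrality delta = d * sqrt(n); power is the probability that
    |T'(df=n-1, delta)| exceeds the central critical value at alpha/2.
    """
    df = q.n - 1
    delta = q.d * math.sqrt(q.n)
    tcrit = sps.t.ppf(1 - q.alpha / 2, df)
    power = sps.nct.sf(tcrit, df, delta) + sps.nct.cdf(-tcrit, df, delta)
    return float(power)


@dataclass(frozen=True)
class CorrelationCI:
    r: float
    n: int
    conf_level: float
    lo: float
    hi: float
    p: float


def fisher_ci(r: float, n: int, conf_level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a correlation, SE = 1/sqrt(n-3)."""
    if n < 4:
        raise ValueError("need n >= 4 for a Fisher-z interval")
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    zc = sps.norm.ppf(0.5 + conf_level / 2)
    return math.tanh(z - zc * se), math.tanh(z + zc * se)


def pearson_with_ci(x: Sequence[float], y: Sequence[float], conf_level: float = 0.95) -> CorrelationCI:
    """Pearson r with two-tailed p and Fisher-z CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise ValueError("need equal-length vectors with n >= 4")
    res = sps.pearsonr(x, y)
    lo, hi = fisher_ci(float(res.statistic), x.size, conf_level)
    return CorrelationCI(float(res.statistic), x.size, conf_level, lo, hi, float(res.pvalue))


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties), two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise ValueError("need equal-length vectors with n >= 4")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def cohens_kappa(a: Sequence[int], b: Sequence[int]) -> float:
    """Cohen's kappa = (p_o - p_e) / (1 - p_e) for two label vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("label vectors must be equal-length and non-empty")
    cats = np.unique(np.concatenate([a, b]))
    n = a.size
    po = float(np.mean(a == b))
    pe = sum(float(np.mean(a == c)) * float(np.mean(b == c)) for c in cats)
    if pe == 1.0:
        raise ValueError("degenerate marginals: chance agreement is 1")
    return (po - pe) / (1 - pe)


def bh_fdr(pvals: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR: (reject flags, adjusted p-values)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    from statsmodels.stats.multitest import multipletests

    reject, p_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject, p_adj


def angular_subtense(half_width: float, distance: float) -> float:
    """Visual angle 2*arctan(half_width/distance) in degrees."""
    if distance <= 0:
        raise ValueError("distance must be positive")
    return float(2.0 * math.degrees(math.atan(half_width / distance)))
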