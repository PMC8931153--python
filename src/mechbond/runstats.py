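"""Run-level statistics: Gaussian fitting of bond-count histograms,
replica aggregation (mean ± sample SD), Pearson correlation and the
pooled two-sample t test."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "GaussianFitResult",
    "RunAggregate",
    "gaussian_fit",
    "aggregate_runs",
    "pearson",
    "t_test_two_sample",
    "significance_stars",
]


@dataclass
class GaussianFitResult:
    amplitude: float
    mu: float
    sigma: float
    r_squared: float


@dataclass
class RunAggregate:
    mean: float
    sd: float
    n: int


def _gauss(x: np.ndarray, a: float, mu: float, sigma: float) -> np.ndarray:
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def gaussian_fit(values: Sequence[float], freqs: Sequence[float]) -> GaussianFitResult:
    """Least-squares Gaussian fit A·exp(−(x−μ)²/2σ²) to a histogram.

    Deterministic moment-based initialisation; requires ≥3 distinct bins
    with nonzero spread.  R² = 1 − SS_res/SS_tot against the frequencies.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(freqs, dtype=float)
    if x.shape != y.shape:
        raise ValueError("values and freqs must be equal-length")
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct histogram bins")
    w = np.clip(y, 0, None)
    if w.sum() <= 0:
        raise ValueError("histogram has no mass")
    mu0 = float(np.average(x, weights=w))
    var0 = float(np.average((x - mu0) ** 2, weights=w))
    if var0 <= 0:
        raise ValueError("histogram has zero variance")
    p0 = (float(y.max()), mu0, np.sqrt(var0))
    popt, _ = optimize.curve_fit(
        _gauss, x, y, p0=p0,
        bounds=([0.0, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    resid = y - _gauss(x, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return GaussianFitResult(
        amplitude=float(popt[0]), mu=float(popt[1]),
        sigma=float(popt[2]), r_squared=r2,
    )


def aggregate_runs(values: Iterable[float]) -> RunAggregate:
    """Arithmetic mean and sample (n−1) standard deviation across replicas."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no values to aggregate")
    sd = float(np.std(arr, ddof=1)) if arr.size >= 2 else float("nan")
    return RunAggregate(mean=float(arr.mean()), sd=sd, n=arr.size)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with its exact two-tailed p-value."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("need equal-length samples with n ≥ 3")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise ValueError("zero variance in one of the samples")
    res = stats.pearsonr(xa, ya)
    return float(res.statistic), float(res.pvalue)


def t_test_two_sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Pooled-variance Student's t (df = n_a + n_b − 2), two-tailed."""
    aa = np.asarray(a, dtype=float)
    bb = np.asarray(b, dtype=float)
    if aa.size < 2 or bb.size < 2:
        raise ValueError("each group needs n ≥ 2")
    if np.var(aa, ddof=1) == 0 and np.var(bb, ddof=1) == 0:
        if aa.mean() == bb.mean():
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t, p = stats.ttest_ind(aa, bb, equal_var=True)
    return float(t), float(p)


def significance_stars(p: float) -> str:
    """Report-layer significance markers at the 0.05/0.01/0.005 levels."""
    if p < 0.005:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
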