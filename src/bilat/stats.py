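"""Population-level statistics: t-tests, the response scatter fit, ratios.

Thin, explicit wrappers around scipy so every reported number carries its
sample size and significance flags, matching the per-test alpha = 0.05
reporting convention (no multiple-testing correction by default; a
Holm-Bonferroni helper is provided for sensitivity checks).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "FitResult",
    "one_sample_t",
    "paired_t",
    "fit_response_scatter",
    "population_ratio",
    "holm_bonferroni",
]


@dataclass(frozen=True)
class TestResult:
    test: str
    n: int
    mean: float
    t: float
    p: float

    @property
    def significant_05(self) -> bool:
        return self.p < 0.05

    @property
    def significant_01(self) -> bool:
        return self.p < 0.01

    @property
    def significant_001(self) -> bool:
        return self.p < 0.001

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(
            significant_05=self.significant_05,
            significant_01=self.significant_01,
            significant_001=self.significant_001,
        )
        return d


@dataclass(frozen=True)
class FitResult:
    slope: float
    intercept: float
    r_squared: float
    slope_ci95: tuple[float, float]
    intercept_stderr: float
    n: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["slope_ci95"] = list(self.slope_ci95)
        return d


def _check_sample(values: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or len(arr) < 2:
        raise ValueError(f"{name} needs at least 2 values")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def one_sample_t(values, mu0: float = 0.0) -> TestResult:
    """Two-sided one-sample Student t-test of the mean against ``mu0``."""
    arr = _check_sample(values, "values")
    if np.ptp(arr) == 0:
        raise ValueError("degenerate sample: zero variance")
    res = sps.ttest_1samp(arr, mu0)
    return TestResult("one-sample-t", len(arr), float(arr.mean()), float(res.statistic), float(res.pvalue))


def paired_t(a, b) -> TestResult:
    """Two-sided paired Student t-test (equivalently a one-sample test on a - b)."""
    x = _check_sample(a, "a")
    y = _check_sample(b, "b")
    if len(x) != len(y):
        raise ValueError("paired test requires equal lengths")
    diff = x - y
    if np.ptp(diff) == 0:
        raise ValueError("degenerate sample: paired differences have zero variance")
    res = sps.ttest_rel(x, y)
    return TestResult("paired-t", len(x), float(diff.mean()), float(res.statistic), float(res.pvalue))


def fit_response_scatter(max_abs_ipsi, max_abs_contra) -> FitResult:
    """OLS fit of per-unit contralateral maxima on ipsilateral maxima.

    ``y = slope * x + intercept`` with R-squared from the residual variance
    and a 95% confidence interval on the slope.
    """
    x = np.asarray(max_abs_ipsi, dtype=float)
    y = np.asarray(max_abs_contra, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired units")
    if np.ptp(x) == 0:
        raise ValueError("constant ipsilateral maxima: slope undefined")
    res = sps.linregress(x, y)
    tcrit = sps.t.ppf(0.975, len(x) - 2)
    return FitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        slope_ci95=(float(res.slope - tcrit * res.stderr), float(res.slope + tcrit * res.stderr)),
        intercept_stderr=float(res.intercept_stderr),
        n=len(x),
    )


def population_ratio(max_abs_ipsi, max_abs_contra) -> float:
    """Ipsilateral-to-contralateral population response ratio, percent.

    ``100 * mean(ipsi maxima) / mean(contra maxima)``.
    """
    ipsi = np.asarray(max_abs_ipsi, dtype=float)
    contra = np.asarray(max_abs_contra, dtype=float)
    denom = contra.mean()
    if denom <= 0:
        raise ValueError("contralateral mean must be positive")
    return float(100.0 * ipsi.mean() / denom)


def holm_bonferroni(pvalues, alpha: float = 0.05) -> list[bool]:
    """Holm step-down rejections (off by default in reporting; sensitivity tool)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    reject = np.zeros(len(p), dtype=bool)
    m = len(p)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject.tolist()
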