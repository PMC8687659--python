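"""Robust trend estimation and rank/binomial tests with a uniform report.

Thin wrappers over scipy's implementations so that every test emitted by
the pipeline carries the same fields: test name, statistic label and
value, two-sided p, and sample sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DataError

__all__ = ["TrendFit", "theil_sen", "rank_tests", "binomial_test"]


@dataclass
class TrendFit:
    """Theil–Sen robust line: slope is the median of all pairwise slopes,
    intercept the median of ``y − slope·x``; p from the Kendall-tau test."""

    slope: float
    intercept: float
    p_value: float
    n: int


def theil_sen(x, y) -> TrendFit:
    """Theil–Sen slope/intercept with a Kendall-tau p-value.

    Robust to gross outliers up to a breakdown point of ~29% of points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise DataError("need at least 3 finite (x, y) pairs")
    if np.all(x == x[0]):
        raise DataError("all x values equal; slope undefined")
    slope, intercept, _, _ = sps.theilslopes(y, x, method="joint")
    tau = sps.kendalltau(x, y)
    p = float(tau.pvalue) if np.isfinite(tau.pvalue) else 1.0
    return TrendFit(slope=float(slope), intercept=float(intercept),
                    p_value=p, n=len(x))


def rank_tests(a, b, paired: bool = False) -> dict:
    """Mann–Whitney U (unpaired) or Wilcoxon signed-rank (paired) report.

    Returns ``{test, statistic, value, p, n}``; degenerate paired input
    (all differences zero) is reported as no-difference rather than an
    error, and groups too small to test are skipped with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired and len(a) != len(b):
        raise DataError("paired arms must have equal length")
    if len(a) < 3 or len(b) < 3:
        warnings.warn("fewer than 3 observations per arm; test skipped")
        return {"test": "wilcoxon_signed_rank" if paired else "mann_whitney_u",
                "statistic": "V" if paired else "U", "value": None,
                "p": None, "n": (len(a), len(b)), "skipped": True}
    if paired:
        diffs = a - b
        if np.allclose(diffs, 0.0):
            return {"test": "wilcoxon_signed_rank", "statistic": "V",
                    "value": 0.0, "p": 1.0, "n": (len(a), len(b)),
                    "degenerate": True}
        res = sps.wilcoxon(a, b)
        return {"test": "wilcoxon_signed_rank", "statistic": "V",
                "value": float(res.statistic), "p": float(res.pvalue),
                "n": (len(a), len(b))}
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return {"test": "mann_whitney_u", "statistic": "U",
            "value": float(res.statistic), "p": float(res.pvalue),
            "n": (len(a), len(b))}


def binomial_test(k: int, n: int, p: float = 0.5) -> dict:
    """Exact two-sided binomial test (minimum-likelihood two-sidedness)."""
    res = sps.binomtest(int(k), int(n), p, alternative="two-sided")
    return {"test": "exact_binomial", "statistic": "k", "value": int(k),
            "p": float(res.pvalue), "n": int(n),
            "proportion": k / n if n else None}
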