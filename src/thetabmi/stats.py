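"""Statistical conventions used throughout: multiple-comparison corrections
and the one-sample test of normalized difference scores against zero."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests


@dataclass
class PvalueSet:
    raw: np.ndarray
    adjusted: np.ndarray
    method: str
    n_tests: int


def bonferroni(p_raw: float, n_tests: int) -> float:
    """Bonferroni adjustment: the raw p-value multiplied by the number of
    tests, capped at 1."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    if not 0 <= p_raw <= 1:
        raise ValueError("p-value must lie in [0, 1]")
    return min(1.0, p_raw * n_tests)


def benjamini_hochberg(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (for many comparisons)."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def adjust(p_raw, method: str = "benjamini_hochberg", n_tests: int | None = None) -> PvalueSet:
    p = np.atleast_1d(np.asarray(p_raw, dtype=float))
    if method == "bonferroni":
        n = n_tests if n_tests is not None else p.size
        adj = np.array([bonferroni(v, n) for v in p])
    elif method == "benjamini_hochberg":
        adj = benjamini_hochberg(p)
    elif method == "none":
        adj = p.copy()
    else:
        raise ValueError(f"unknown method {method!r}")
    return PvalueSet(raw=p, adjusted=adj, method=method,
                     n_tests=n_tests if n_tests is not None else p.size)


def diff_score_ttest(scores) -> tuple[float, float]:
    """Two-sided one-sample t-test of difference scores against a zero null."""
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 scores")
    if np.std(s, ddof=1) == 0:
        raise ValueError("zero variance: t statistic undefined")
    t, p = sstats.ttest_1samp(s, 0.0)
    return float(t), float(p)
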