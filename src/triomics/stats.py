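"""Shared statistical primitives: multiple testing, two-sample tests,
hypergeometric enrichment, and count normalization."""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: Optional[float] = None

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class EnrichmentResult:
    k: int
    n: int
    K: int
    N: int
    p_value: float
    fdr: Optional[float] = None


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Classical pooled-variance (Student) two-sided t-test.

    Degenerate zero pooled variance: equal means give t=0, p=1; unequal means
    give p=0 with a warning (the statistic is reported as signed infinity).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = a.size, b.size
    df = na + nb - 2
    diff = a.mean() - b.mean()
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if sp2 == 0.0:
        if diff == 0.0:
            return TestResult(0.0, 1.0, df)
        warnings.warn("zero pooled variance with unequal means; p = 0")
        return TestResult(float(np.sign(diff)) * np.inf, 0.0, df)
    t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(min(p, 1.0)), df)


def hypergeom_enrich(k: int, n: int, K: int, N: int) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment: P(X >= k) for X ~ HG(N, K, n).

    Equals a one-sided Fisher's exact test on the 2x2 overlap table.
    ``k`` = overlap, ``n`` = query size, ``K`` = annotated-set size,
    ``N`` = universe size.
    """
    if min(k, n, K, N) < 0 or n > N or K > N:
        raise ValueError("inconsistent counts: need 0 <= n, K <= N")
    if k > min(n, K) or k < max(0, n + K - N):
        raise ValueError("overlap k outside the feasible range")
    p = float(sps.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(k, n, K, N, min(p, 1.0))


def median_of_ratios(counts, reference_cols=None) -> np.ndarray:
    """Per-sample size factors by the median-of-ratios method.

    ``counts`` is a gene x sample non-negative matrix (array or DataFrame).
    Ratios are taken to the per-gene geometric mean over genes whose counts are
    positive in every sample; at least one such gene is required.

    ``reference_cols`` optionally restricts the geometric-mean reference to a
    column subset (positional indices).  In IP/input designs referencing the
    input samples keeps enrichment of a sizeable gene minority from leaking
    into the size factors; the default (all samples) is the classical
    estimator.
    """
    mat = np.asarray(counts, dtype=float)
    if mat.ndim != 2:
        raise ValueError("counts must be a 2-D gene x sample matrix")
    if np.any(mat < 0):
        raise ValueError("counts must be non-negative")
    all_pos = np.all(mat > 0, axis=1)
    if not np.any(all_pos):
        raise ValueError("no gene has positive counts in all samples")
    sub = mat[all_pos]
    ref = sub if reference_cols is None else sub[:, list(reference_cols)]
    log_geomean = np.mean(np.log(ref), axis=1)
    factors = np.exp(np.median(np.log(sub) - log_geomean[:, None], axis=0))
    return factors
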