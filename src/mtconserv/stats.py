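"""Comparative statistics over conservation-index distributions.

Thin, explicit wrappers over scipy: two-sample Kolmogorov-Smirnov
(asymptotic p by default, permutation p on request — the defensible
choice for heavily tied discrete indices), Student's pooled-variance
t-test (Welch optional), and a chi-square goodness of fit of the index
distributions against a maximum-likelihood exponential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    df: float | None = None
    n: tuple[int, ...] = ()

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of range: {self.p_value}")


def ks_two_sample(
    x, y, permutation: bool = False, n_permutations: int = 2000,
    seed: int | None = None,
) -> TestResult:
    """Two-sided two-sample KS test (D = sup |ECDF_x - ECDF_y|)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("KS test requires non-empty samples")
    if permutation:
        d_obs = sps.ks_2samp(x, y, method="asymp").statistic
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([x, y])
        n = len(x)
        count = 0
        for _ in range(n_permutations):
            rng.shuffle(pooled)
            d = sps.ks_2samp(pooled[:n], pooled[n:], method="asymp").statistic
            if d >= d_obs - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
        return TestResult("ks_permutation", float(d_obs), float(p),
                          n=(len(x), len(y)))
    res = sps.ks_2samp(x, y, method="asymp")
    return TestResult("ks", float(res.statistic),
                      float(min(1.0, res.pvalue)), n=(len(x), len(y)))


def two_sample_t(x, y, pooled: bool = True) -> TestResult:
    """Student's pooled-variance t by default (df = n1+n2-2); Welch as
    an option."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) + len(y) < 3:
        raise ValueError("t-test requires at least three observations")
    ss = sum(((v - v.mean()) ** 2).sum() for v in (x, y))
    if pooled and ss == 0:
        raise ValueError("zero pooled variance")
    res = sps.ttest_ind(x, y, equal_var=pooled)
    df = len(x) + len(y) - 2 if pooled else float(res.df)
    return TestResult("t" if pooled else "t_welch", float(res.statistic),
                      float(res.pvalue), df=float(df), n=(len(x), len(y)))


def exponential_gof(values, n_bins: int = 16) -> TestResult:
    """Chi-square fit of values against an ML exponential.

    Equal-width bins over [0, max] with an open tail bin; the rate is
    1/mean, so df = n_bins - 2.  Values must be non-negative (shift
    scores to positive support before calling).
    """
    v = np.asarray(values, dtype=float)
    if n_bins < 3:
        raise ValueError("need at least 3 bins")
    if np.any(v < 0):
        raise ValueError("exponential fit requires non-negative values")
    n = len(v)
    rate = 1.0 / v.mean()
    edges = np.linspace(0.0, v.max(), n_bins)  # last bin open-ended
    cdf = 1.0 - np.exp(-rate * edges)
    probs = np.diff(np.concatenate([cdf, [1.0]]))
    observed = np.histogram(v, bins=np.concatenate([edges, [np.inf]]))[0]
    expected = n * probs
    ok = expected > 0
    chi2 = float(((observed[ok] - expected[ok]) ** 2 / expected[ok]).sum())
    df = int(ok.sum()) - 2
    p = float(sps.chi2.sf(chi2, df))
    return TestResult("exponential_gof", chi2, p, df=df, n=(n,))
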