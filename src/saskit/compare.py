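"""Statistical comparison of scattering curves.

Two curves measured from the same sample should differ only by noise.
Three tests are provided:

* the reduced chi-square test, which needs trustworthy error estimates;
* the correlation-map (CORMAP) longest-run test, which needs none: under
  the null hypothesis the signs of the pointwise differences are fair
  coin flips, and the length of the longest same-sign run has an exactly
  computable distribution;
* a paired Student t-test on the standardized differences, for reference.

The longest-run null distribution is evaluated with exact integer
arithmetic (run-limited composition counting), valid for n up to 1e4
and beyond without overflow or loss of the tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats

from .curve import ScatteringCurve
from .curve_ops import _check_common_grid

__all__ = [
    "Chi2Result",
    "CormapResult",
    "reduced_chi2",
    "longest_run_pvalue",
    "cormap_test",
    "ttest_paired",
    "compare_set",
]


@dataclass
class Chi2Result:
    chi2_reduced: float
    dof: int
    n_points: int
    p_value: float


@dataclass
class CormapResult:
    n: int
    longest_run: int
    p_value: float


def _combined_sigma(a: ScatteringCurve, b: ScatteringCurve) -> np.ndarray:
    if a.sigma is not None and b.sigma is not None:
        return np.hypot(a.sigma, b.sigma)
    if a.sigma is not None:
        return a.sigma
    if b.sigma is not None:
        return b.sigma
    raise ValueError("reduced chi-square requires sigma on at least one curve")


def reduced_chi2(
    a: ScatteringCurve, b: ScatteringCurve, dof_extra: int = 0
) -> Chi2Result:
    """Reduced chi-square between two curves on a common grid.

    chi2_red = (1/nu) * sum (I_a - I_b)^2 / sigma^2 with
    nu = n - 1 - dof_extra; when both curves carry errors they are
    combined in quadrature. The p-value is the upper tail of the
    chi-square distribution with nu degrees of freedom.
    """
    _check_common_grid([a, b])
    sigma = _combined_sigma(a, b)
    n = len(a)
    nu = n - 1 - dof_extra
    if nu < 1:
        raise ValueError("fewer than 1 degree of freedom")
    statistic = float(np.sum(((a.i - b.i) / sigma) ** 2))
    chi2_red = statistic / nu
    p = float(stats.chi2.sf(statistic, nu))
    return Chi2Result(chi2_reduced=chi2_red, dof=nu, n_points=n, p_value=p)


def _count_runs_bounded(n: int, max_run: int) -> int:
    """Number of binary strings of length n whose runs are all <= max_run.

    Equals 2 * (compositions of n into parts <= max_run): the run-length
    sequence is a composition and the first symbol can be either sign.
    Computed with exact integers via the sliding-window recurrence.
    """
    if max_run <= 0:
        return 0
    if max_run >= n:
        return 2**n
    # c[j] = compositions of j into parts of size 1..max_run
    c = [0] * (n + 1)
    c[0] = 1
    window = 0  # running sum c[j-max_run] + ... + c[j-1]
    for j in range(1, n + 1):
        window += c[j - 1]
        if j - max_run - 1 >= 0:
            window -= c[j - max_run - 1]
        c[j] = window
    return 2 * c[n]


def longest_run_pvalue(n: int, c: int) -> float:
    """Exact P(longest same-sign run >= c) in n fair Bernoulli trials.

    This is the CORMAP null: the probability that n independent fair
    coin flips contain at least one run of c or more equal outcomes.
    Exact rational arithmetic, converted to float at the end.
    """
    if not (1 <= c <= n):
        raise ValueError(f"require 1 <= c <= n, got c={c}, n={n}")
    if c == 1:
        return 1.0
    good = _count_runs_bounded(n, c - 1)
    return float(1 - Fraction(good, 2**n))


def longest_run_length(signs: np.ndarray) -> int:
    """Length of the longest constant run in a sign sequence."""
    signs = np.asarray(signs)
    best = cur = 1
    for k in range(1, len(signs)):
        cur = cur + 1 if signs[k] == signs[k - 1] else 1
        best = max(best, cur)
    return best


def cormap_test(a: ScatteringCurve, b: ScatteringCurve) -> CormapResult:
    """CORMAP comparison of two curves on a common grid.

    The test statistic is the longest same-sign run of I_a - I_b; exact
    zero differences are assigned positive sign (deterministic; real
    data essentially never tie). The p-value is exact under the
    fair-sign null.
    """
    _check_common_grid([a, b])
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 points")
    signs = np.where(a.i - b.i >= 0, 1, -1)
    c = longest_run_length(signs)
    return CormapResult(n=n, longest_run=c, p_value=longest_run_pvalue(n, c))


def ttest_paired(a: ScatteringCurve, b: ScatteringCurve) -> tuple[float, float]:
    """Paired Student t-test on standardized differences (reference only).

    Tests whether the mean of (I_a - I_b)/sigma differs from zero.
    Returns (t statistic, two-sided p-value).
    """
    _check_common_grid([a, b])
    z = (a.i - b.i) / _combined_sigma(a, b)
    t, p = stats.ttest_1samp(z, 0.0)
    return float(t), float(p)


def compare_set(
    curves: list[ScatteringCurve],
    method: str = "cormap",
    adjustment: str = "bonferroni",
) -> np.ndarray:
    """All-pairs comparison with multiple-testing adjustment.

    Returns the symmetric k x k matrix of (adjusted) p-values with unit
    diagonal. Bonferroni multiplies each raw p by the number of pairs
    m = k(k-1)/2 and caps at 1.
    """
    k = len(curves)
    if k < 2:
        raise ValueError("need at least 2 curves")
    _check_common_grid(curves)
    if method not in ("cormap", "chi2", "ttest"):
        raise ValueError(f"unknown method {method!r}")
    if adjustment not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    m = k * (k - 1) // 2
    factor = m if adjustment == "bonferroni" else 1
    out = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if method == "cormap":
                p = cormap_test(curves[i], curves[j]).p_value
            elif method == "chi2":
                p = reduced_chi2(curves[i], curves[j]).p_value
            else:
                p = ttest_paired(curves[i], curves[j])[1]
            out[i, j] = out[j, i] = min(1.0, factor * p)
    return out
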