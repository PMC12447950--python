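"""Quantification statistics for cell-count and fluorescence comparisons.

Implements the small statistical toolkit used to compare hair-cell and
nonsensory-cell counts between genotypes: one- and two-sided two-sample
t-tests (Welch by default, pooled optional), Cohen's d with post-hoc power
from the noncentral t distribution, and the one-sided Fisher exact test for
proportions of neuromasts with at least one regenerated hair cell.

Everything is computed from first principles; ``scipy`` supplies only the
(noncentral) t distribution functions and ``gammaln``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy import stats as sps

__all__ = [
    "TestResult",
    "t_test",
    "cohens_d",
    "power_from_d",
    "fisher_one_sided",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample comparison.

    ``df`` is real-valued to accommodate the Welch–Satterthwaite correction;
    ``sided`` is ``"one"`` (direction a > b) or ``"two"``. ``d`` and
    ``power`` are filled in when an effect size is computable.
    """

    statistic: float
    df: float
    p_value: float
    sided: str
    d: float | None = None
    power: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


def _as_group(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size < 2:
        raise ValueError("each group needs at least 2 units")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite measurement in group")
    return a


def t_test(a, b, sided: str = "two", pooled: bool = False,
           alpha: float = 0.05, compute_power: bool = True) -> TestResult:
    """Two-sample t-test of group ``a`` against group ``b``.

    By default the unequal-variance (Welch) statistic with
    Welch–Satterthwaite degrees of freedom; ``pooled=True`` uses the
    classical equal-variance statistic. The one-sided alternative is
    ``mean(a) > mean(b)``. Returns Cohen's d and the post-hoc power at
    ``alpha`` alongside the test.
    """
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    x, y = _as_group(a), _as_group(b)
    na, nb = x.size, y.size
    va, vb = x.var(ddof=1), y.var(ddof=1)
    diff = x.mean() - y.mean()

    if va == 0.0 and vb == 0.0:
        if diff == 0.0:
            warnings.warn("zero variance in both groups with equal means; p = 1")
            return TestResult(0.0, float(na + nb - 2), 1.0, sided, d=0.0,
                              power=alpha)
        raise ValueError("zero variance in both groups with unequal means")

    if pooled:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = float(na + nb - 2)
    else:
        se = math.sqrt(va / na + vb / nb)
        num = (va / na + vb / nb) ** 2
        den = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        df = num / den
    t = diff / se

    if sided == "two":
        p = 2.0 * sps.t.sf(abs(t), df)
    else:
        p = float(sps.t.sf(t, df))
    p = min(1.0, float(p))

    d, power = None, None
    if compute_power:
        try:
            d = cohens_d(x, y)
            power = power_from_d(d, na, nb, alpha=alpha, sided=sided)
        except ValueError:
            pass
    return TestResult(float(t), float(df), p, sided, d=d, power=power)


def cohens_d(a, b) -> float:
    """Standardized mean difference (mean_a − mean_b) / pooled SD."""
    x, y = _as_group(a), _as_group(b)
    na, nb = x.size, y.size
    sp2 = ((na - 1) * x.var(ddof=1) + (nb - 1) * y.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0.0:
        raise ValueError("zero pooled standard deviation")
    return float((x.mean() - y.mean()) / math.sqrt(sp2))


def power_from_d(d: float, n_a: int, n_b: int, alpha: float = 0.05,
                 sided: str = "two") -> float:
    """Power of the two-sample t-test at effect size ``d``.

    Uses the noncentral t distribution with noncentrality
    d·sqrt(n_a·n_b/(n_a+n_b)) and n_a+n_b−2 degrees of freedom. One-sided
    power is taken in the direction of the effect's sign.
    """
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    if min(n_a, n_b) < 2:
        raise ValueError("each group needs at least 2 units")
    df = n_a + n_b - 2
    ncp = d * math.sqrt(n_a * n_b / (n_a + n_b))
    if sided == "two":
        tcrit = sps.t.isf(alpha / 2.0, df)
        power = sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp)
    else:
        tcrit = sps.t.isf(alpha, df)
        power = sps.nct.sf(tcrit, df, abs(ncp))
    return float(min(1.0, max(0.0, power)))


def _log_comb(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)


def fisher_one_sided(table) -> float:
    """One-sided Fisher exact test for a greater proportion in row 1.

    ``table`` is a 2×2 array of nonnegative integers
    ``[[a, b], [c, d]]`` where columns are (event, no event) and rows are
    the two groups. Returns the hypergeometric tail probability
    P(X ≥ a) with X the (1,1) cell under fixed margins. A zero row or
    column margin leaves a single achievable table, so p = 1.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(np.int64)
        if np.any(t < 0):
            raise ValueError("table entries must be nonnegative integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    row1, col1, total = a + b, a + c, a + b + c + d
    if row1 == 0 or col1 == 0 or (c + d) == 0 or (b + d) == 0:
        return 1.0
    k_max = min(row1, col1)
    ks = np.arange(a, k_max + 1)
    log_p = (_log_comb(col1, ks) + _log_comb(total - col1, row1 - ks)
             - _log_comb(total, row1))
    return float(min(1.0, np.exp(log_p).sum()))
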