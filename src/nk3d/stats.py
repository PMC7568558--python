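"""Statistical procedures used throughout the analysis.

* Chromium-release lysis fraction,
  (experimental - spontaneous) / (maximum - spontaneous).
* Exact paired Wilcoxon signed-rank test: for small samples (n <= 12 after
  dropping zero differences) the two-sided p is computed by enumerating all
  2^n sign assignments of the observed mid-ranks, which stays exact under
  ties; larger samples use the normal approximation with tie correction.
* Spearman rank-order correlation with a t-based test statistic,
  t = rho * sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom, which avoids
  over-rejection at small n.
* Power-law fits f(x) = a * x^b by ordinary least squares in log–log space,
  with R^2 computed on the log–log residuals and a t-test of b = 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import InvalidAssayError, UndefinedStatisticError

__all__ = [
    "StatResult",
    "PowerLawFit",
    "lysis_fraction",
    "wilcoxon_signed_rank_exact",
    "spearman_t",
    "powerlaw_fit",
]

EXACT_ENUMERATION_MAX_N = 12


@dataclass
class StatResult:
    method: str
    statistic: float
    p: float
    n: int
    notes: str = ""


@dataclass
class PowerLawFit:
    """Fit of f(x) = a * x^b; R^2 and the slope test live in log–log space."""

    a: float
    b: float
    r_squared: float
    b_se: float
    b_p: float
    n: int


def lysis_fraction(experimental: float, spontaneous: float,
                   maximum: float) -> float:
    """Specific lysis of a chromium-release assay.

    May fall outside [0, 1] on noisy input; the value is returned unclamped
    (with a warning) so downstream analyses see the raw assay readout.
    """
    if maximum <= spontaneous:
        raise InvalidAssayError("maximum release must exceed spontaneous release")
    frac = (experimental - spontaneous) / (maximum - spontaneous)
    if not 0.0 <= frac <= 1.0:
        warnings.warn(f"lysis fraction {frac:.3f} outside [0, 1]", stacklevel=2)
    return frac


def _signed_ranks(differences: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mid-ranks of |d| and the signs, after dropping zero differences."""
    d = differences[differences != 0]
    ranks = sps.rankdata(np.abs(d))
    return ranks, np.sign(d)


def wilcoxon_signed_rank_exact(pairs: Sequence[tuple[float, float]]) -> StatResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped; tied absolute differences receive
    mid-ranks.  For n <= 12 the p-value is exact: all 2^n sign assignments
    of the observed ranks are enumerated, and the two-sided p is twice the
    smaller tail of W+ (capped at 1), conditioning on the observed rank
    pattern.  Above n = 12 a normal approximation with tie correction is
    used.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
        raise UndefinedStatisticError("need at least one (a, b) pair")
    diffs = arr[:, 0] - arr[:, 1]
    ranks, signs = _signed_ranks(diffs)
    n = ranks.size
    if n == 0:
        warnings.warn("all differences are zero; p = 1", stacklevel=2)
        return StatResult("wilcoxon_signed_rank", 0.0, 1.0, 0,
                          notes="all differences zero")
    w_plus = float(ranks[signs > 0].sum())
    if n <= EXACT_ENUMERATION_MAX_N:
        w_all = _enumerate_w(ranks)
        p_low = np.mean(w_all <= w_plus + 1e-9)
        p_high = np.mean(w_all >= w_plus - 1e-9)
        p = min(1.0, 2.0 * min(p_low, p_high))
        notes = f"exact enumeration over 2^{n} sign assignments"
    else:
        mu = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(counts ** 3 - counts)) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_plus - mu) / math.sqrt(var)
        p = 2.0 * sps.norm.sf(abs(z))
        notes = "normal approximation with tie correction"
    return StatResult("wilcoxon_signed_rank", w_plus, float(p), n, notes)


def _enumerate_w(ranks: np.ndarray) -> np.ndarray:
    """W+ under every sign assignment of the given ranks (2^n values)."""
    n = ranks.size
    # Subset sums via binary counting on a (2^n, n) mask — n <= 12 keeps
    # this at most 4096 x 12.
    masks = (np.arange(2 ** n)[:, None] >> np.arange(n)) & 1
    return masks @ ranks


def spearman_t(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Spearman rank correlation with a t-distribution based p-value.

    rho is the Pearson correlation of the mid-ranked data; the two-sided p
    comes from t = rho*sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom.
    At |rho| = 1 the t statistic diverges and the p-value is reported as
    the permutation-enumeration limit 2/n!.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise UndefinedStatisticError("need n >= 3 paired values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedStatisticError("correlation undefined for constant input")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0 - 1e-12:
        p = 2.0 / math.factorial(n)
        return StatResult("spearman_t", math.copysign(1.0, rho), p, n,
                          notes="|rho| = 1; p is the permutation limit 2/n!")
    t = rho * math.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return StatResult("spearman_t", rho, float(p), n, notes=f"t = {t:.4f}")


def powerlaw_fit(x: Sequence[float], y: Sequence[float]) -> PowerLawFit:
    """Fit f(x) = a * x^b by OLS of ln y on ln x.

    R^2 is computed on the log–log residuals; when ln y has zero variance
    (constant y) R^2 is reported as 0.  ``b_p`` is the two-sided t-test of
    b = 0 (NaN for n = 2, where the fit is exact).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise UndefinedStatisticError("need >= 2 paired values")
    if np.any(x <= 0) or np.any(y <= 0):
        raise UndefinedStatisticError("power-law fit requires positive x and y")
    lx, ly = np.log(x), np.log(y)
    n = x.size
    X = np.column_stack([np.ones(n), lx])
    coef, *_ = np.linalg.lstsq(X, ly, rcond=None)
    resid = ly - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if n > 2:
        s2 = ss_res / (n - 2)
        sxx = float(((lx - lx.mean()) ** 2).sum())
        b_se = math.sqrt(s2 / sxx)
        if b_se > 0:
            t = coef[1] / b_se
            b_p = 2.0 * sps.t.sf(abs(t), df=n - 2)
        else:
            b_p = 0.0 if coef[1] != 0 else 1.0
    else:
        b_se, b_p = float("nan"), float("nan")
    return PowerLawFit(a=float(np.exp(coef[0])), b=float(coef[1]),
                       r_squared=float(r2), b_se=float(b_se),
                       b_p=float(b_p), n=n)
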