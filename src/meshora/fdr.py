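"""Multiple-testing correction: BH, Q-value and local FDR.

Three views of the same mixture model. Under the two-groups model a
fraction pi0 of hypotheses are null with Uniform(0,1) p-values and the
rest come from an alternative concentrated near zero.

* ``bh_adjust`` — Benjamini-Hochberg step-up: q_i = p_(i) * m / i on the
  sorted p-values, monotonized by a running minimum from the largest
  rank. Assumes pi0 = 1, hence conservative.
* ``qvalue_adjust`` — scales the BH values by an estimate of pi0
  obtained from the p-value histogram: Storey's lambda-grid tail counts
  smoothed with a natural cubic spline and read off at the largest
  lambda.
* ``local_fdr`` — the per-hypothesis posterior null probability
  pi0 * f0(p) / f(p) with f0 = 1 and f estimated by the Grenander
  (monotone non-increasing) density estimator, i.e. the left derivative
  of the least concave majorant of the empirical CDF.

The spline degrees of freedom, the lambda grid and the Grenander choice
are concrete realizations of methods the literature describes at a
higher level; each sits behind its operation so it can be swapped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._errors import ValidationError

_LAMBDA_GRID = np.arange(0.05, 0.901, 0.05)
_MIN_M_FOR_PI0 = 20


def _validate_pvalues(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p-value vector must be one-dimensional and non-empty")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return p


@dataclass(frozen=True)
class Pi0Estimate:
    """Estimated proportion of true null hypotheses."""

    pi0: float
    lambda_grid: tuple[float, ...] = ()
    method_note: str = ""


@dataclass(frozen=True)
class AdjustedPvalues:
    """Adjusted values aligned to the input order, with reject calls at
    ``alpha`` (adjusted < alpha)."""

    method: str
    values: np.ndarray
    alpha: float
    rejected: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.rejected is None:
            object.__setattr__(self, "rejected", self.values < self.alpha)


def bh_adjust(pvalues, alpha: float = 0.05) -> AdjustedPvalues:
    """Benjamini-Hochberg step-up adjusted p-values.

    On the ascending-sorted sequence, q_i = p_(i) * m / i, followed by a
    running minimum from the largest rank down (step-up monotonization)
    and capping at 1; results are mapped back to the input order. The
    rejection set at level alpha is every hypothesis with adjusted value
    strictly below alpha, which reproduces the classic "largest k with
    p_(k) <= alpha*k/m" rule.
    """
    p = _validate_pvalues(pvalues)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    # p * (m/i), not (p*m)/i: keeps q exactly p when m == i and avoids
    # spurious strict-inequality flips at round thresholds
    ranked = p[order] * (m / np.arange(1, m + 1))
    monotone = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(monotone, 1.0)
    return AdjustedPvalues(method="BH", values=adjusted, alpha=alpha)


def _natural_cubic_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (truncated-power construction with
    linearity constraints beyond the boundary knots)."""

    def d(k: int) -> np.ndarray:
        num = np.clip(x - knots[k], 0, None) ** 3 - np.clip(x - knots[-1], 0, None) ** 3
        return num / (knots[-1] - knots[k])

    cols = [np.ones_like(x), x]
    for k in range(len(knots) - 2):
        cols.append(d(k) - d(len(knots) - 2))
    return np.column_stack(cols)


def estimate_pi0(pvalues) -> Pi0Estimate:
    """Storey-style pi0 from lambda-grid tail counts with spline smoothing.

    pi0(lambda) = #{p > lambda} / (m * (1 - lambda)) on lambda = 0.05,
    0.10, ..., 0.90; a natural cubic spline with 3 degrees of freedom is
    fitted to pi0(lambda) against lambda and evaluated at the largest
    lambda, then clamped to (0, 1]. Fewer than 20 p-values, or a
    degenerate all-equal vector, fall back to pi0 = 1.
    """
    p = _validate_pvalues(pvalues)
    m = p.size
    grid = _LAMBDA_GRID
    if m < _MIN_M_FOR_PI0:
        return Pi0Estimate(1.0, tuple(grid), "fallback: fewer than 20 p-values")
    if np.all(p == p[0]):
        warnings.warn("degenerate all-equal p-value vector; pi0 set to 1")
        return Pi0Estimate(1.0, tuple(grid), "fallback: degenerate p-value vector")

    pi0_lambda = np.array([np.mean(p > lam) / (1.0 - lam) for lam in grid])
    # 3 df -> 3 basis functions -> 3 knots (boundary + 1 interior)
    knots = np.quantile(grid, [0.0, 0.5, 1.0])
    basis = _natural_cubic_basis(grid, knots)
    coef, *_ = np.linalg.lstsq(basis, pi0_lambda, rcond=None)
    at_max = float((_natural_cubic_basis(np.array([grid[-1]]), knots) @ coef)[0])
    pi0 = min(1.0, max(at_max, 1.0 / m))
    return Pi0Estimate(pi0, tuple(grid), "Storey lambda grid + natural cubic spline (3 df)")


def qvalue_adjust(
    pvalues, alpha: float = 0.05, pi0: float | None = None
) -> AdjustedPvalues:
    """Q-values: the BH adjusted values scaled by the estimated pi0.

    Q_i = pi0 * p_(i) * m / i with the same step-up monotonization; with
    pi0 = 1 this reduces exactly to BH. ``pi0`` may be supplied to
    bypass estimation.
    """
    p = _validate_pvalues(pvalues)
    if pi0 is None:
        pi0 = estimate_pi0(p).pi0
    if not 0 < pi0 <= 1:
        raise ValidationError(f"pi0 must lie in (0, 1], got {pi0}")
    bh = bh_adjust(p, alpha=alpha)
    values = np.minimum(pi0 * bh.values, 1.0)
    return AdjustedPvalues(method="QV", values=values, alpha=alpha)


def _grenander_density(p_sorted: np.ndarray) -> np.ndarray:
    """Grenander estimate f(p_i) for sorted p: slopes of the least
    concave majorant of the empirical CDF over [0, 1]."""
    m = p_sorted.size
    x = np.concatenate(([0.0], p_sorted, [1.0]))
    y = np.concatenate(([0.0], np.arange(1, m + 1) / m, [1.0]))
    # collapse duplicate x (tied p-values) keeping the largest y
    x_unique, last_idx = np.unique(x, return_index=True)
    # np.unique returns first occurrence; for ties we need the max y
    y_unique = np.maximum.reduceat(y, last_idx)
    # upper concave hull by monotone-slope stack
    hull = [0]
    for i in range(1, len(x_unique)):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            s_prev = (y_unique[i2] - y_unique[i1]) / (x_unique[i2] - x_unique[i1])
            s_new = (y_unique[i] - y_unique[i2]) / (x_unique[i] - x_unique[i2])
            if s_new >= s_prev:
                hull.pop()
            else:
                break
        hull.append(i)
    hx = x_unique[hull]
    hy = y_unique[hull]
    slopes = np.diff(hy) / np.diff(hx)
    seg = np.clip(np.searchsorted(hx, p_sorted, side="left") - 1, 0, len(slopes) - 1)
    return slopes[seg]


def local_fdr(
    pvalues, alpha: float = 0.05, pi0: float | None = None
) -> AdjustedPvalues:
    """Local FDR: pi0 * f0(p) / f(p) with f0 = 1 and f the Grenander
    monotone density estimate; values clamped to [0, 1].

    Requires at least 20 p-values — density estimation below that is
    meaningless; use BH instead.
    """
    p = _validate_pvalues(pvalues)
    if p.size < _MIN_M_FOR_PI0:
        raise ValidationError(
            "local FDR needs at least 20 p-values; use bh_adjust for small families"
        )
    if pi0 is None:
        pi0 = estimate_pi0(p).pi0
    order = np.argsort(p, kind="mergesort")
    f_hat = _grenander_density(p[order])
    lfdr_sorted = np.clip(pi0 / np.maximum(f_hat, 1e-300), 0.0, 1.0)
    # enforce monotone non-decreasing lfdr in p (f is non-increasing, but
    # guard against flat-segment ties)
    lfdr_sorted = np.maximum.accumulate(lfdr_sorted)
    values = np.empty_like(lfdr_sorted)
    values[order] = lfdr_sorted
    return AdjustedPvalues(method="lFDR", values=values, alpha=alpha)


@dataclass(frozen=True)
class PvalueDiagnostics:
    """Advisory summary of a p-value distribution."""

    decile_counts: tuple[int, ...]
    ks_statistic: float
    ks_pvalue: float
    looks_uniform: bool


def choose_method_diagnostics(pvalues) -> PvalueDiagnostics:
    """Decile histogram plus a Kolmogorov-Smirnov distance from the
    Uniform(0,1) null; advisory only — callers pick the correction that
    suits the observed shape."""
    p = _validate_pvalues(pvalues)
    counts, _ = np.histogram(p, bins=10, range=(0.0, 1.0))
    ks = stats.kstest(p, "uniform")
    return PvalueDiagnostics(
        decile_counts=tuple(int(c) for c in counts),
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        looks_uniform=bool(ks.pvalue > 0.05),
    )


#: Dispatch table used by the enrichment engine.
ENGINES = {
    "none": None,
    "BH": bh_adjust,
    "QV": qvalue_adjust,
    "lFDR": local_fdr,
}
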