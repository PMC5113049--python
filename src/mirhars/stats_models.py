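"""Statistical primitives for the univariate predictive models.

Each candidate miRNA is analyzed separately: a pooled-variance two-sample
t-test compares group means of normalized expression, and an unconditional
(univariate) logistic regression of HARS class on normalized CT yields the
odds ratio, Wald 95% CI and p, plus the concordance.

Concordance is the c-statistic: over all case–control pairs, the fraction in
which the fitted score of the case exceeds that of the control, ties counted
half.  It is invariant under strictly monotone transforms of the score, and
equals 1 exactly at complete separation.

Complete separation — the predictor perfectly ordering the two classes —
makes logistic maximum-likelihood estimates diverge, so no Wald p exists.
Those p-values are replaced by a frequency-distribution comparison: the
predictor is dichotomized at the pooled median and a Pearson chi-square
(1 df, no continuity correction) is computed on the resulting 2x2 table.
The median-split construction is this package's documented choice of
"frequency distribution comparison"; the split rule is an explicit argument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import expit

__all__ = [
    "GroupComparison",
    "students_t_test",
    "LogisticFit",
    "fit_logistic",
    "concordance",
    "detect_separation",
    "chisq_fallback_p",
    "bonferroni_flags",
    "ConvergenceError",
]

#: z-quantile for the Wald 95% confidence interval.
WALD_Z = 1.959964

#: |slope| beyond which the maximum-likelihood estimate is treated as
#: divergent (quasi-separation escape hatch during IRLS).
SEPARATION_BETA_LIMIT = 15.0


class ConvergenceError(RuntimeError):
    """IRLS failed to converge on a non-separated data set."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class GroupComparison:
    """Descriptive statistics and two-sided t-test for one group contrast.

    ``minimum``/``maximum`` span the pooled values of both groups.
    ``degenerate`` flags the all-values-identical case, where p = 1 by
    convention.
    """

    n_case: int
    n_ref: int
    mean_case: float
    mean_ref: float
    sd_case: float
    sd_ref: float
    minimum: float
    maximum: float
    t_stat: float
    t_p: float
    degenerate: bool = False


def students_t_test(x: Sequence[float], y: Sequence[float]) -> GroupComparison:
    """Pooled-variance (Student's) two-sample t-test, case ``x`` vs ref ``y``.

    Two-sided p from the t distribution with n_x + n_y − 2 df.  Equal
    variances are assumed per the classical test (Welch is available through
    scipy directly for sensitivity analyses but is not the default here).
    When every value in both groups is identical the statistic is 0 and
    p = 1 by convention, flagged ``degenerate``; when the groups are
    constant but different the p-value degenerates to 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two values for a t-test")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("t-test inputs must be finite")

    nx, ny = x.size, y.size
    mx, my = float(np.mean(x)), float(np.mean(y))
    sx, sy = float(np.std(x, ddof=1)), float(np.std(y, ddof=1))
    pooled = np.concatenate([x, y])
    df = nx + ny - 2
    sp2 = ((nx - 1) * sx**2 + (ny - 1) * sy**2) / df
    degenerate = False
    if sp2 == 0.0:
        if mx == my:
            t_stat, t_p, degenerate = 0.0, 1.0, True
        else:
            t_stat = math.inf if mx > my else -math.inf
            t_p = 0.0
    else:
        se = math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
        t_stat = (mx - my) / se
        t_p = 2.0 * float(stats.t.sf(abs(t_stat), df))
    return GroupComparison(
        n_case=nx,
        n_ref=ny,
        mean_case=mx,
        mean_ref=my,
        sd_case=sx,
        sd_ref=sy,
        minimum=float(np.min(pooled)),
        maximum=float(np.max(pooled)),
        t_stat=t_stat,
        t_p=t_p,
        degenerate=degenerate,
    )


def concordance(scores: Sequence[float], y: Sequence[int]) -> float:
    """c-statistic of ``scores`` against binary labels ``y`` (1 = case).

    Computed from the Mann–Whitney U via midranks, which is exactly pair
    counting with half-credit ties.  Raises on a single-class ``y``.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("concordance requires both classes present")
    ranks = stats.rankdata(scores)
    u = float(np.sum(ranks[y == 1])) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def detect_separation(x: Sequence[float], y: Sequence[int]) -> bool:
    """True iff the predictor perfectly orders the classes.

    Strict ordering is required: a value shared across the two classes (a
    tied cross-class pair) breaks complete separation, matching the
    concordance-equals-1-without-ties characterization.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    case = x[y == 1]
    ctrl = x[y == 0]
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("detect_separation requires both classes present")
    return bool(case.max() < ctrl.min() or ctrl.max() < case.min())


def _chisq_2x2(table: np.ndarray) -> tuple[float, float, bool]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table.

    Returns (statistic, p, degenerate).  A zero margin makes the statistic
    undefined; p = 1 by convention, flagged degenerate.
    """
    table = np.asarray(table, dtype=float)
    a, b = table[0]
    c, d = table[1]
    n = a + b + c + d
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins) or n == 0:
        return 0.0, 1.0, True
    stat = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(stats.chi2.sf(stat, 1))
    return float(stat), p, False


def chisq_fallback_p(
    x: Sequence[float], y: Sequence[int], split: str = "median"
) -> float:
    """Fallback p-value by frequency-distribution comparison.

    The predictor is dichotomized at the pooled median (> median vs
    <= median), crossed with the class labels into a 2x2 table, and tested
    with a Pearson chi-square (1 df, no continuity correction), two-sided.
    Degenerate tables (a zero margin) yield p = 1.
    """
    if split != "median":
        raise ValueError(f"unknown split rule {split!r}; only 'median' is implemented")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.sum(y == 1) == 0 or np.sum(y == 0) == 0:
        raise ValueError("chisq_fallback_p requires both classes present")
    cut = float(np.median(x))
    high = x > cut
    table = np.array(
        [
            [np.sum((y == 1) & high), np.sum((y == 1) & ~high)],
            [np.sum((y == 0) & high), np.sum((y == 0) & ~high)],
        ],
        dtype=float,
    )
    _, p, _ = _chisq_2x2(table)
    return p


@dataclass(frozen=True)
class LogisticFit:
    """Univariate logistic fit summary on the log-odds-per-ΔCT-cycle scale.

    When ``separated`` is true the maximum-likelihood estimate diverges:
    coefficient, OR and CI fields are None, no Wald p is emitted, and the
    reported ``p`` comes from the chi-square fallback
    (``p_source == "chisq_fallback"``).
    """

    beta0: float | None
    beta1: float | None
    or_value: float | None
    ci_low: float | None
    ci_high: float | None
    wald_p: float | None
    p: float
    p_source: str
    concordance: float
    separated: bool
    n_iter: int
    converged: bool


def _irls(
    x: np.ndarray, y: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, int, bool, bool, list[float]]:
    """Newton/IRLS for the two-parameter logistic model.

    Returns (beta, fisher_info, n_iter, converged, diverged, ll_trace);
    ``diverged`` is set when |beta1| exceeds the separation limit, the
    signature of a non-existent MLE.
    """
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    ll = _loglik(X, beta, y)
    trace = [ll]
    H = _fisher(X, beta)
    for it in range(1, max_iter + 1):
        mu = expit(X @ beta)
        grad = X.T @ (y - mu)
        H = _fisher(X, beta)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, H, it, False, True, trace
        # Step-halving keeps the likelihood monotone if Newton overshoots.
        new_beta = beta + step
        new_ll = _loglik(X, new_beta, y)
        halvings = 0
        while new_ll < ll and halvings < 25:
            step *= 0.5
            new_beta = beta + step
            new_ll = _loglik(X, new_beta, y)
            halvings += 1
        beta = new_beta
        trace.append(new_ll)
        if abs(beta[1]) > SEPARATION_BETA_LIMIT:
            return beta, H, it, False, True, trace
        if abs(new_ll - ll) < tol:
            return beta, _fisher(X, beta), it, True, False, trace
        ll = new_ll
    return beta, H, max_iter, False, False, trace


def _loglik(X: np.ndarray, beta: np.ndarray, y: np.ndarray) -> float:
    eta = X @ beta
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _fisher(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    mu = expit(X @ beta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    return (X * w[:, None]).T @ X


def fit_logistic(
    x: Sequence[float],
    y: Sequence[int],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFit:
    """Maximum-likelihood univariate logistic regression with separation care.

    The fit uses iteratively reweighted least squares (Newton) with
    step-halving, converging on an absolute log-likelihood change below
    ``tol``.  OR = exp(beta1); the 95% CI is exp(beta1 ± 1.959964·SE); the
    Wald p tests beta1²/SE² against chi-square(1).

    Separation is declared either by the exact ordering test
    (:func:`detect_separation`) before fitting, or when |beta1| escapes past
    ``SEPARATION_BETA_LIMIT`` during iteration (quasi-separation).  Separated
    fits report the chi-square-fallback p and carry no Wald quantities.
    A constant predictor carries no information: beta1 = 0, OR = 1,
    concordance 0.5, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("y must be binary 0/1")
    if np.sum(y == 1) == 0 or np.sum(y == 0) == 0:
        raise ValueError("fit_logistic requires both classes present")
    if not np.all(np.isfinite(x)):
        raise ValueError("predictor values must be finite")

    if np.ptp(x) == 0.0:
        return LogisticFit(
            beta0=float(math.log(np.mean(y) / (1 - np.mean(y)))),
            beta1=0.0,
            or_value=1.0,
            ci_low=None,
            ci_high=None,
            wald_p=1.0,
            p=1.0,
            p_source="wald",
            concordance=0.5,
            separated=False,
            n_iter=0,
            converged=True,
        )

    if detect_separation(x, y):
        return LogisticFit(
            beta0=None,
            beta1=None,
            or_value=None,
            ci_low=None,
            ci_high=None,
            wald_p=None,
            p=chisq_fallback_p(x, y),
            p_source="chisq_fallback",
            concordance=1.0,
            separated=True,
            n_iter=0,
            converged=False,
        )

    beta, info, n_iter, converged, diverged, trace = _irls(x, y, tol, max_iter)
    if diverged:
        # Quasi-separation: the MLE runs away although strict ordering fails
        # (e.g. a boundary tie).  Report the fallback p; the concordance is
        # the honest pair-counting value, which may sit just below 1.
        scores = beta[0] + beta[1] * x
        return LogisticFit(
            beta0=None,
            beta1=None,
            or_value=None,
            ci_low=None,
            ci_high=None,
            wald_p=None,
            p=chisq_fallback_p(x, y),
            p_source="chisq_fallback",
            concordance=concordance(scores, y),
            separated=True,
            n_iter=n_iter,
            converged=False,
        )
    if not converged:
        raise ConvergenceError(
            f"IRLS did not converge in {n_iter} iterations "
            f"(last log-likelihoods: {trace[-5:]})",
            trace,
        )

    cov = np.linalg.inv(info)
    se1 = math.sqrt(cov[1, 1])
    beta1 = float(beta[1])
    wald_stat = (beta1 / se1) ** 2 if se1 > 0 else math.inf
    wald_p = float(stats.chi2.sf(wald_stat, 1))
    scores = beta[0] + beta1 * x
    return LogisticFit(
        beta0=float(beta[0]),
        beta1=beta1,
        or_value=math.exp(beta1),
        ci_low=math.exp(beta1 - WALD_Z * se1),
        ci_high=math.exp(beta1 + WALD_Z * se1),
        wald_p=wald_p,
        p=wald_p,
        p_source="wald",
        concordance=concordance(scores, y),
        separated=False,
        n_iter=n_iter,
        converged=True,
    )


def bonferroni_flags(
    pvals: Sequence[float], alpha: float = 0.05
) -> tuple[float, list[bool]]:
    """Per-comparison threshold alpha/m and strict-< survival flags.

    With a family of 20 hypotheses at family alpha 0.05 the threshold is
    0.0025; with 15 it is ~0.0033.  Only p-values strictly below the
    threshold survive.
    """
    m = len(pvals)
    if m == 0:
        raise ValueError("bonferroni_flags requires at least one p-value")
    threshold = alpha / m
    return threshold, [p < threshold for p in pvals]
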