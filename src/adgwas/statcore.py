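"""Self-contained statistical estimators shared by every pipeline stage.

The regression fitters are written here rather than delegated because the
pipeline contracts pin down their behaviour exactly: iteratively reweighted
least squares with a fixed score-norm convergence rule for logistic models,
Breslow handling of tied event times for the Cox partial likelihood, and
explicit non-convergence flags for separated or monotone-likelihood data.
Rank tests, exact tests and quantiles wrap scipy/numpy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "FitResult",
    "RankTestResult",
    "QuantileBoundaries",
    "SingularDesignError",
    "logistic_fit",
    "wald_or_ci",
    "wilcoxon_rank_sum",
    "cox_ph_fit",
    "hwe_exact_test",
    "quantile_boundaries",
]

#: Interior tolerance on the score (gradient) max-norm for IRLS / Newton.
SCORE_TOL = 1e-8
MAX_ITER_LOGISTIC = 25
MAX_ITER_COX = 50


class SingularDesignError(ValueError):
    """Design matrix is rank deficient (e.g. a constant non-intercept column)."""


@dataclass
class FitResult:
    """Maximum-likelihood fit of a regression model on the log-odds or log-hazard scale."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    covariance: np.ndarray
    log_likelihood: float
    converged: bool
    n_iterations: int
    names: list[str] | None = None

    def z_values(self) -> np.ndarray:
        return self.coefficients / self.standard_errors

    def p_values(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z_values()))

    def term(self, name: str) -> tuple[float, float]:
        """(coefficient, se) for a named model term."""
        if self.names is None:
            raise ValueError("fit carries no term names")
        i = self.names.index(name)
        return float(self.coefficients[i]), float(self.standard_errors[i])


@dataclass
class RankTestResult:
    """Two-sample Wilcoxon rank-sum test result.

    ``statistic`` is the rank-sum of the first sample; ``mode`` records whether
    the p-value came from exact enumeration or the tie/continuity-corrected
    normal approximation.
    """

    statistic: float
    p_value: float
    medians: tuple[float, float]
    n1: int
    n2: int
    mode: str = "asymptotic"
    degenerate: bool = False


@dataclass
class QuantileBoundaries:
    """Interior quantile cut-points at probabilities i/k (linear interpolation)."""

    cuts: np.ndarray
    k: int
    degenerate: bool = False


def _validate_design(design: np.ndarray) -> np.ndarray:
    x = np.asarray(design, dtype=float)
    if x.ndim != 2:
        raise ValueError("design must be a 2-D matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("design contains non-finite values")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise SingularDesignError("design matrix is rank deficient")
    return x


def logistic_fit(design: np.ndarray, outcome: np.ndarray,
                 names: list[str] | None = None) -> FitResult:
    """Fit a logistic regression by IRLS.

    The caller supplies the intercept column. Wald standard errors come from
    the observed information at the optimum. Perfect separation surfaces as a
    non-converged result (diverging coefficients, score never below tolerance),
    never as silent garbage.
    """
    x = _validate_design(design)
    y = np.asarray(outcome, dtype=float)
    n, p = x.shape
    if y.shape != (n,):
        raise ValueError("outcome length does not match design")
    if n < p:
        raise ValueError("fewer rows than parameters")
    if not (np.any(y == 0) and np.any(y == 1)):
        raise ValueError("outcome must contain both classes")

    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, MAX_ITER_LOGISTIC + 1):
        eta = np.clip(x @ beta, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = x.T @ (y - mu)
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        info = (x * w[:, None]).T @ x
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:  # weights collapsed
            raise SingularDesignError("information matrix singular") from exc
        beta = beta + step

    eta = np.clip(x @ beta, -30.0, 30.0)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = (x * w[:, None]).T @ x
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    ll = float(np.sum(y * np.log(np.clip(mu, 1e-300, 1)) +
                      (1 - y) * np.log(np.clip(1 - mu, 1e-300, 1))))
    se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    if _diverged(beta, se):
        converged = False  # separation: score vanishes only by link saturation
    return FitResult(beta, se, cov, ll, converged, it, names)


def _diverged(beta: np.ndarray, se: np.ndarray) -> bool:
    """Heuristic for separation / monotone likelihood: the score can vanish
    with the estimate at infinity, where the information collapses and the
    Wald se explodes relative to the coefficient."""
    return bool(np.any(~np.isfinite(se)) or
                np.any(se > 100.0 * (1.0 + np.abs(beta))))


def wald_or_ci(beta: float, se: float, level: float = 0.95) -> tuple[float, float, float]:
    """Odds ratio with a Wald confidence interval: exp(beta -/+ z*se)."""
    if se < 0:
        raise ValueError("standard error must be non-negative")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return math.exp(beta), math.exp(beta - z * se), math.exp(beta + z * se)


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> RankTestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    ``mode`` is one of ``auto`` (exact when n1+n2 <= 12 and tie-free, else
    asymptotic), ``exact`` or ``asymptotic``. The asymptotic p uses the tie
    correction and a continuity correction. The statistic reported is the
    rank-sum of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    medians = (float(np.median(x)), float(np.median(y)))

    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # every observation identical: no evidence either way
        w = n1 * (n1 + n2 + 1) / 2.0
        return RankTestResult(w, 1.0, medians, n1, n2, "degenerate", True)

    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        mode = "exact" if (n1 + n2 <= 12 and not has_ties) else "asymptotic"
    if mode == "exact" and has_ties:
        raise ValueError("exact mode is only defined for tie-free data")

    method = "exact" if mode == "exact" else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    w = float(res.statistic) + n1 * (n1 + 1) / 2.0  # U1 -> rank-sum of x
    return RankTestResult(w, float(min(res.pvalue, 1.0)), medians, n1, n2, mode)


def _cox_loglik(beta, times, event, x):
    """Breslow log partial likelihood with gradient and information.

    Rows must be sorted by descending time so that risk-set sums are prefix
    cumulative sums.
    """
    eta = x @ beta
    eta = np.clip(eta, -200, 200)
    r = np.exp(eta)
    # prefix cumsums over the (descending-time) ordering = risk-set sums
    s0 = np.cumsum(r)
    s1 = np.cumsum(x * r[:, None], axis=0)
    p = x.shape[1]
    s2 = np.cumsum(r[:, None, None] * (x[:, :, None] * x[:, None, :]), axis=0)

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    n = times.size
    while i < n:
        j = i
        while j + 1 < n and times[j + 1] == times[i]:
            j += 1
        # risk set for this time = rows 0..j (ties enter their own risk set)
        ev = event[i:j + 1].astype(bool)
        d = int(ev.sum())
        if d:
            xe = x[i:j + 1][ev]
            S0, S1, S2 = s0[j], s1[j], s2[j]
            ll += float(eta[i:j + 1][ev].sum() - d * math.log(S0))
            grad += xe.sum(axis=0) - d * S1 / S0
            info += d * (S2 / S0 - np.outer(S1, S1) / S0**2)
        i = j + 1
    return ll, grad, info


def cox_ph_fit(time, event, covariates, names: list[str] | None = None) -> FitResult:
    """Cox proportional-hazards fit by Newton-Raphson on the Breslow partial likelihood.

    Tied event times are handled with the Breslow approximation. Hazard ratios
    are exp(coefficient). Monotone likelihood (e.g. one group's events all
    preceding the other's) is reported as a non-converged result.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=float)
    x = np.asarray(covariates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if np.any(t <= 0):
        raise ValueError("all times must be positive")
    if not np.any(e == 1):
        raise ValueError("at least one event is required")
    if np.linalg.matrix_rank(x - x.mean(axis=0)) < x.shape[1]:
        raise SingularDesignError("constant or collinear covariate")

    # canonical ordering (descending time, then event and covariates) so that
    # permuting input rows leaves every floating-point sum, hence the whole
    # result, bit-identical
    order = np.lexsort(tuple(x[:, j] for j in range(x.shape[1] - 1, -1, -1))
                       + (e, -t))
    ts, es, xs = t[order], e[order], x[order]
    xbar = xs.mean(axis=0)
    xc = xs - xbar  # centering for numerical stability; shift-invariant model

    p = x.shape[1]
    beta = np.zeros(p)
    converged = False
    it = 0
    ll = -np.inf
    for it in range(1, MAX_ITER_COX + 1):
        ll, grad, info = _cox_loglik(beta, ts, es, xc)
        if np.max(np.abs(grad)) < SCORE_TOL:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            converged = False
            break
        # dampen huge steps (monotone-likelihood divergence stays flagged)
        norm = np.max(np.abs(step))
        if norm > 5.0:
            step *= 5.0 / norm
        beta = beta + step

    _, _, info = _cox_loglik(beta, ts, es, xc)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    if _diverged(beta, se):
        converged = False  # monotone partial likelihood
    return FitResult(beta, se, cov, float(ll), converged, it, names)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the probabilities that are no larger than that of the observed
    configuration (two-sided by probability ordering).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("total count must be positive")
    n_a = 2 * n_aa + n_Aa  # minor-allele copies (either allele works: symmetric)
    n_a = min(n_a, 2 * n - n_a)
    if n_a == 0:
        return 1.0

    # unnormalized probabilities over heterozygote counts with the same parity
    hets = np.arange(n_a % 2, n_a + 1, 2)
    logp = np.empty(hets.size)
    for idx, h in enumerate(hets):
        rare_hom = (n_a - h) // 2
        common_hom = n - rare_hom - h
        logp[idx] = (h * math.log(2)
                     - math.lgamma(rare_hom + 1)
                     - math.lgamma(common_hom + 1)
                     - math.lgamma(h + 1))
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = int(np.where(hets == n_Aa)[0][0])
    return float(min(1.0, prob[prob <= prob[obs] * (1 + 1e-12)].sum()))


def quantile_boundaries(values, k: int) -> QuantileBoundaries:
    """k-1 interior empirical quantile cut-points at probabilities i/k.

    Linear interpolation between order statistics; the result is flagged
    degenerate when there are fewer than k distinct values.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("values must be non-empty")
    if k < 2:
        raise ValueError("k must be >= 2")
    probs = np.arange(1, k) / k
    cuts = np.quantile(v, probs, method="linear")
    degenerate = np.unique(v).size < k
    return QuantileBoundaries(np.asarray(cuts, dtype=float), k, degenerate)
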