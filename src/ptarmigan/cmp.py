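"""Mean-parameterized Conway–Maxwell–Poisson (CMP) distribution.

The CMP distribution generalizes the Poisson with a dispersion parameter
``nu``: ``P(Y = j) ∝ lambda^j / (j!)^nu``. With ``nu > 1`` the variance falls
below the mean (underdispersion, typical of clutch sizes); ``nu = 1``
recovers the Poisson; ``nu < 1`` gives overdispersion. The natural rate
``lambda`` has no direct mean interpretation, so the regression code works on
the mean scale: ``solve_lambda`` inverts the mean relation numerically.

All normalizing-constant arithmetic is done in log space over an adaptive
truncated support.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln, logsumexp

from .errors import ConvergenceError, ValidationError

__all__ = [
    "cmp_log_normalizer",
    "cmp_pmf",
    "cmp_mean_var",
    "solve_lambda",
    "cmp_rvs",
]

_MAX_SUPPORT = 10_000
_TAIL_TOL = 1e-12


def _support_bound(lam: np.ndarray, nu: float) -> int:
    """Truncation point: far enough beyond the mode that the tail is < 1e-12."""
    mode = np.max(np.power(lam, 1.0 / nu))
    bound = int(mode + 20.0 * math.sqrt(mode / nu + 1.0) + 30.0)
    return min(max(bound, 50), _MAX_SUPPORT)


def _log_terms(lam, nu: float, j: np.ndarray) -> np.ndarray:
    """log(lambda^j / (j!)^nu) for a grid j; broadcasts lam against j."""
    lam = np.asarray(lam, dtype=float)
    return np.multiply.outer(np.log(lam), j) - nu * gammaln(j + 1.0)


def _validated(lam, nu: float) -> np.ndarray:
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    if nu <= 0 or not math.isfinite(nu):
        raise ValidationError(f"nu must be positive and finite, got {nu}")
    if np.any(lam <= 0) or not np.all(np.isfinite(lam)):
        raise ValidationError("lambda must be positive and finite")
    return lam


def cmp_log_normalizer(lam, nu: float):
    """log Z(lambda, nu) = log sum_{j>=0} lambda^j / (j!)^nu.

    Accumulated in log space; the series is truncated once the remaining
    terms are negligible (relative tail < 1e-12, support capped at 10^4).
    Vectorized over ``lam``.
    """
    lam_arr = _validated(lam, nu)
    j = np.arange(_support_bound(lam_arr, nu) + 1, dtype=float)
    lt = _log_terms(lam_arr, nu, j)
    logz = logsumexp(lt, axis=-1)
    # Guard: last term must be far below the accumulated sum.
    if np.any(lt[..., -1] - logz > math.log(_TAIL_TOL)):
        raise ConvergenceError(
            "CMP normalizer truncation did not converge",
            diagnostics={"nu": nu, "lam_max": float(lam_arr.max())},
        )
    return logz if np.ndim(lam) else float(logz[0])


def cmp_mean_var(lam, nu: float) -> tuple[np.ndarray, np.ndarray]:
    """Mean and variance of CMP(lambda, nu) by direct summation."""
    lam_arr = _validated(lam, nu)
    j = np.arange(_support_bound(lam_arr, nu) + 1, dtype=float)
    lt = _log_terms(lam_arr, nu, j)
    logz = logsumexp(lt, axis=-1, keepdims=True)
    p = np.exp(lt - logz)
    mean = p @ j
    var = p @ (j * j) - mean**2
    if np.ndim(lam):
        return mean, var
    return float(mean[0]), float(var[0])


def solve_lambda(mu, nu: float, tol: float = 1e-8, max_iter: int = 100):
    """Invert the CMP mean relation: find lambda with mean(lambda, nu) = mu.

    Safeguarded Newton iteration on log(lambda); the derivative of the mean
    with respect to log(lambda) is the variance, which is strictly positive,
    so the mean is monotone and the root is unique.
    """
    mu_arr = np.atleast_1d(np.asarray(mu, dtype=float))
    if np.any(mu_arr <= 0) or not np.all(np.isfinite(mu_arr)):
        raise ValidationError("mu must be positive and finite")
    if nu <= 0 or not math.isfinite(nu):
        raise ValidationError(f"nu must be positive and finite, got {nu}")

    # Asymptotic approximation (good start for moderate mu):
    # lambda ~ (mu + (nu - 1) / (2 nu)) ** nu
    loglam = nu * np.log(np.maximum(mu_arr + (nu - 1.0) / (2.0 * nu), 1e-8))
    lo = np.full_like(loglam, -np.inf)
    hi = np.full_like(loglam, np.inf)
    for _ in range(max_iter):
        mean, var = cmp_mean_var(np.exp(loglam), nu)
        resid = mean - mu_arr
        if np.all(np.abs(resid) < tol):
            lam = np.exp(loglam)
            return lam if np.ndim(mu) else float(lam[0])
        lo = np.where(resid < 0, np.maximum(lo, loglam), lo)
        hi = np.where(resid > 0, np.minimum(hi, loglam), hi)
        step = resid / np.maximum(var, 1e-12)
        new = loglam - np.clip(step, -5.0, 5.0)
        # Bisect wherever Newton leaves the current bracket.
        bad = (new <= lo) | (new >= hi)
        mid = np.where(
            np.isfinite(lo) & np.isfinite(hi),
            0.5 * (lo + hi),
            np.where(np.isfinite(lo), lo + 1.0, hi - 1.0),
        )
        loglam = np.where(bad, mid, new)
    raise ConvergenceError(
        "CMP mean inversion failed to converge",
        diagnostics={"nu": nu, "max_resid": float(np.max(np.abs(resid)))},
    )


def cmp_pmf(y, mu, nu: float):
    """CMP probability mass at counts ``y`` for mean ``mu`` and dispersion ``nu``."""
    y_arr = np.atleast_1d(np.asarray(y, dtype=float))
    if np.any(y_arr < 0) or np.any(y_arr != np.floor(y_arr)):
        raise ValidationError("counts must be non-negative integers")
    lam = solve_lambda(float(mu), nu)
    logz = cmp_log_normalizer(lam, nu)
    logp = y_arr * math.log(lam) - nu * gammaln(y_arr + 1.0) - logz
    p = np.exp(logp)
    return p if np.ndim(y) else float(p[0])


def cmp_rvs(mu, nu: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Sample counts from CMP(mu, nu) by inverse-CDF over the truncated support."""
    lam = solve_lambda(float(mu), nu)
    j = np.arange(_support_bound(np.atleast_1d(lam), nu) + 1, dtype=float)
    lt = _log_terms(lam, nu, j)
    p = np.exp(lt - logsumexp(lt))
    cdf = np.cumsum(p)
    u = rng.random(size)
    return np.searchsorted(cdf, u).astype(int)
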