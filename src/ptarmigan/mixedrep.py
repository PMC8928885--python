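"""Random-intercept linear mixed model, repeatability, and parametric bootstrap.

Repeatability (intraclass correlation) of a behavior is the share of the
total phenotypic variance attributable to differences between individuals:

    R = sigma_alpha^2 / (sigma_alpha^2 + sigma_eps^2)

where ``sigma_alpha^2`` is the between-bird (random-intercept) variance and
``sigma_eps^2`` the residual variance of a linear mixed model. "Agreement"
repeatability uses an intercept-only fixed part; "adjusted" repeatability
conditions on fixed covariates (here: age class). Confidence intervals come
from a parametric bootstrap: new responses are simulated from the fitted
normal components, the model is refit, and percentile bounds are taken over
the bootstrap distribution of R.

The REML fit profiles the variance ratio ``theta = sigma_alpha^2 /
sigma_eps^2``: for fixed theta the GLS fixed effects and the residual
variance have closed forms via per-group sufficient statistics, leaving a
one-dimensional restricted-likelihood search over theta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from .errors import ConvergenceError, ValidationError

__all__ = [
    "LmmFit",
    "RepeatabilityResult",
    "RandomInterceptLMM",
    "fit_lmm",
    "repeatability",
    "bootstrap_ci",
    "agreement_and_adjusted",
]


@dataclass(frozen=True)
class LmmFit:
    """REML fit of ``y = X beta + alpha_group + eps``."""

    beta: np.ndarray
    sigma2_alpha: float
    sigma2_eps: float
    reml_loglik: float
    n_obs: int
    n_groups: int

    def __post_init__(self):
        if self.sigma2_alpha < 0 or self.sigma2_eps < 0:
            raise ValidationError("variance components must be non-negative")


@dataclass(frozen=True)
class RepeatabilityResult:
    R: float
    ci_low: float
    ci_high: float
    kind: str  # "agreement" | "adjusted"
    n_boot: int
    seed: int
    n_failed: int = 0


class RandomInterceptLMM(BaseEstimator):
    """Linear mixed model with a single random intercept, fit by REML.

    Parameters
    ----------
    tol : float
        Absolute tolerance of the 1-D profiled search over the log variance
        ratio.

    Attributes (after ``fit``)
    --------------------------
    coef_ : ndarray — GLS fixed-effect estimates at the REML optimum.
    sigma2_alpha_ : float — between-group variance.
    sigma2_eps_ : float — residual variance.
    reml_loglik_ : float — restricted log-likelihood at the optimum.
    n_obs_, n_groups_ : int.
    """

    def __init__(self, tol: float = 1e-10):
        self.tol = tol

    def fit(self, X, y, groups):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n, p = X.shape
        if len(y) != n or len(groups) != n:
            raise ValidationError("X, y and groups must have matching lengths")
        if np.linalg.matrix_rank(X) < p:
            raise ValidationError("fixed-effect design is singular (rank-deficient)")
        _, gidx, counts = np.unique(np.asarray(groups), return_inverse=True, return_counts=True)
        g = len(counts)
        if g < 2:
            raise ValidationError("at least 2 groups are required")
        if counts.max() < 2:
            raise ValidationError(
                "all groups are singletons; between/within variances are not separable"
            )

        # Per-group sufficient statistics.
        sx = np.zeros((g, p))
        np.add.at(sx, gidx, X)
        sy = np.bincount(gidx, weights=y, minlength=g)
        xtx = X.T @ X
        xty = X.T @ y
        yty = float(y @ y)
        nc = counts.astype(float)

        def profile(theta: float):
            """Profiled REML: returns (-2 restricted loglik, beta, s2_eps)."""
            c = theta / (1.0 + theta * nc)
            xvx = xtx - (sx * c[:, None]).T @ sx
            xvy = xty - sx.T @ (c * sy)
            yvy = yty - float(c @ (sy**2))
            beta = np.linalg.solve(xvx, xvy)
            q = max(yvy - float(beta @ xvy), 0.0)
            s2_eps = q / (n - p)
            if s2_eps <= 0:  # exact fit; restricted likelihood unbounded
                s2_eps = np.finfo(float).tiny
            sign, logdet_xvx = np.linalg.slogdet(xvx)
            neg2 = (
                (n - p) * (np.log(s2_eps) + 1.0 + np.log(2.0 * np.pi))
                + float(np.sum(np.log1p(theta * nc)))
                + logdet_xvx
            )
            return neg2, beta, s2_eps

        res = minimize_scalar(
            lambda t: profile(np.exp(t))[0],
            bounds=(-30.0, 16.0),
            method="bounded",
            options={"xatol": self.tol},
        )
        cand = [(res.fun, float(np.exp(res.x)))]
        cand.append((profile(0.0)[0], 0.0))  # boundary: no between-group variance
        neg2, theta = min(cand, key=lambda c: c[0])
        _, beta, s2_eps = profile(theta)

        self.coef_ = beta
        self.sigma2_eps_ = float(s2_eps)
        self.sigma2_alpha_ = float(theta * s2_eps)
        self.reml_loglik_ = -0.5 * neg2
        self.n_obs_ = n
        self.n_groups_ = g
        return self

    def repeatability(self) -> float:
        """R = sigma_alpha^2 / (sigma_alpha^2 + sigma_eps^2)."""
        total = self.sigma2_alpha_ + self.sigma2_eps_
        if total <= 0:
            raise ValidationError("total variance is zero; repeatability undefined")
        return self.sigma2_alpha_ / total

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return X @ self.coef_


def fit_lmm(y, X, groups, tol: float = 1e-10) -> LmmFit:
    """Functional wrapper: REML fit returning an :class:`LmmFit`."""
    est = RandomInterceptLMM(tol=tol).fit(X, y, groups)
    return LmmFit(
        beta=est.coef_,
        sigma2_alpha=est.sigma2_alpha_,
        sigma2_eps=est.sigma2_eps_,
        reml_loglik=est.reml_loglik_,
        n_obs=est.n_obs_,
        n_groups=est.n_groups_,
    )


def repeatability(fit: LmmFit) -> float:
    """Repeatability from variance components; errors on zero total variance."""
    total = fit.sigma2_alpha + fit.sigma2_eps
    if total <= 0:
        raise ValidationError("total variance is zero; repeatability undefined")
    return fit.sigma2_alpha / total


def bootstrap_ci(
    y,
    X,
    groups,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    kind: str = "agreement",
) -> RepeatabilityResult:
    """Parametric-bootstrap percentile CI for repeatability.

    Each replicate simulates responses from the fitted model — group
    intercepts ``N(0, sigma2_alpha)`` and residuals ``N(0, sigma2_eps)``
    added to the fixed-effect mean — refits by REML, and recomputes R.
    Replicates whose refit fails are recorded and skipped; more than 10%
    failures aborts.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    fit = fit_lmm(y, X, groups)
    r_hat = repeatability(fit)
    _, gidx = np.unique(np.asarray(groups), return_inverse=True)
    mean = X @ fit.beta
    sa = np.sqrt(fit.sigma2_alpha)
    se = np.sqrt(fit.sigma2_eps)
    rng = np.random.default_rng(seed)

    draws = np.empty(n_boot)
    failed = 0
    kept = 0
    for _ in range(n_boot):
        alpha = rng.normal(0.0, sa, fit.n_groups)
        y_star = mean + alpha[gidx] + rng.normal(0.0, se, fit.n_obs)
        try:
            draws[kept] = repeatability(fit_lmm(y_star, X, groups))
            kept += 1
        except (ValidationError, ConvergenceError, np.linalg.LinAlgError):
            failed += 1
    if failed > 0.1 * n_boot:
        raise ConvergenceError(
            "more than 10% of bootstrap refits failed",
            diagnostics={"failed": failed, "n_boot": n_boot},
        )
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws[:kept], [tail, 1.0 - tail])
    return RepeatabilityResult(
        R=r_hat,
        ci_low=float(lo),
        ci_high=float(hi),
        kind=kind,
        n_boot=n_boot,
        seed=seed,
        n_failed=failed,
    )


def agreement_and_adjusted(
    transitions,
    birds,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[RepeatabilityResult, RepeatabilityResult]:
    """Agreement and age-adjusted repeatability of log movement distance.

    Only birds with two or more observed seasonal decisions enter the model.
    The response is ``log(distance_m + 1)``; the +1 m offset accommodates
    true zero displacements and sits orders of magnitude below migrant
    distances. Agreement uses an intercept-only fixed part; adjusted adds an
    adult-age indicator.
    """
    tr = transitions.merge(
        birds[["bird_id", "age_class"]], on="bird_id", how="left", validate="many_to_one"
    )
    counts = tr.groupby("bird_id")["distance_m"].transform("size")
    tr = tr[counts >= 2]
    if tr["bird_id"].nunique() < 2:
        raise ValidationError("fewer than 2 birds with repeated decisions; repeatability undefined")
    y = np.log(tr["distance_m"].to_numpy(dtype=float) + 1.0)
    groups = tr["bird_id"].to_numpy()
    n = len(y)
    x_agree = np.ones((n, 1))
    adult = (tr["age_class"].to_numpy() == "adult").astype(float)
    x_adj = np.column_stack([np.ones(n), adult])
    agree = bootstrap_ci(y, x_agree, groups, n_boot=n_boot, seed=seed, level=level, kind="agreement")
    adj = bootstrap_ci(y, x_adj, groups, n_boot=n_boot, seed=seed + 1, level=level, kind="adjusted")
    return agree, adj
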