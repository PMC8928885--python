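"""First-spring regression models and AICc model selection.

Four analyses, each over a small candidate set ranked by AICc:

* migratory decision (migrant = 1) ~ weight, age — binomial GLM, logit link;
* log movement distance ~ weight, age — Gaussian linear model;
* clutch size ~ strategy, age, weight — mean-parameterized
  Conway–Maxwell–Poisson regression with log link (clutch sizes are
  typically underdispersed, ``nu > 1``);
* nest fate (hatched = 1) ~ strategy, age, weight — binomial GLM.

Body weight is standardized (z-scored) on the analysis subset. Parameter
counts for AICc include every estimated parameter: the Gaussian residual
variance and the CMP dispersion each add one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp
from sklearn.base import BaseEstimator

from .cmp import _log_terms, _support_bound, solve_lambda
from .errors import ConvergenceError, SeparationWarning, ValidationError

__all__ = [
    "GlmFit",
    "BinomialGLM",
    "GaussianGLM",
    "CMPRegression",
    "standardize",
    "fit_binomial",
    "fit_gaussian",
    "fit_cmp_regression",
    "aicc",
    "rank_models",
    "run_candidate_sets",
]


def standardize(x) -> np.ndarray:
    """Z-scores: (x - mean) / sd with the n-1 (sample) denominator."""
    x = np.asarray(x, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValidationError("standardize needs at least 2 distinct values")
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd


@dataclass
class GlmFit:
    """A fitted fixed-effects model, uniform across families.

    ``loglik`` is the full maximum likelihood (not REML/deviance), so AICc
    values are comparable across candidate models; ``k`` counts every
    estimated parameter including dispersion/variance terms.
    """

    family: str  # "binomial-logit" | "gaussian-identity" | "cmp-log"
    params: dict[str, float]
    loglik: float
    k: int
    n: int
    extra: dict = field(default_factory=dict)

    @property
    def coef(self) -> np.ndarray:
        return np.array(list(self.params.values()))


class BinomialGLM(BaseEstimator):
    """Binomial GLM with logit link, fit by iteratively reweighted least squares.

    Attributes after ``fit``: ``coef_``, ``loglik_``, ``k_``, ``n_``,
    ``n_iter_``, ``separation_``.
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n, p = X.shape
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValidationError("binomial response must be 0/1")
        if len(np.unique(y)) < 2:
            raise ValidationError("both outcome classes must be present")
        if np.linalg.matrix_rank(X) < p:
            raise ValidationError("design matrix is rank-deficient")

        beta = np.zeros(p)
        self.separation_ = False
        for it in range(1, self.max_iter + 1):
            eta = X @ beta
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1.0 - mu)
            grad = X.T @ (y - mu)
            if np.linalg.norm(grad) < self.tol:
                break
            xtwx = (X * w[:, None]).T @ X
            try:
                step = np.linalg.solve(xtwx, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(xtwx, grad, rcond=None)[0]
            beta = beta + step
            if np.max(np.abs(X @ beta)) > 30.0:
                self.separation_ = True
                warnings.warn(
                    "complete or quasi-complete separation: coefficients diverging",
                    SeparationWarning,
                )
                break
        eta = X @ beta
        if not self.separation_ and np.max(np.abs(eta)) > 15.0:
            # Gradient can vanish numerically while coefficients run off to
            # +/- infinity; fitted probabilities indistinguishable from 0/1
            # signal quasi-complete separation.
            self.separation_ = True
            warnings.warn(
                "complete or quasi-complete separation: fitted probabilities at 0/1",
                SeparationWarning,
            )
        self.coef_ = beta
        self.loglik_ = float(np.sum(y * eta - np.log1p(np.exp(eta))))
        self.k_ = p
        self.n_ = n
        self.n_iter_ = it
        return self

    def predict_proba(self, X):
        eta = np.asarray(X, dtype=float) @ self.coef_
        p1 = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)


class GaussianGLM(BaseEstimator):
    """Gaussian linear model (identity link) reporting the full-ML log-likelihood.

    The residual variance is an estimated parameter, so ``k_ = p + 1``. An
    exact fit (zero residual variance) is flagged via ``degenerate_`` and
    carries an infinite log-likelihood rather than an error.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n, p = X.shape
        if n <= p:
            raise ValidationError(f"need n > k: n={n}, p={p}")
        if np.linalg.matrix_rank(X) < p:
            raise ValidationError("design matrix is rank-deficient")
        res = sm.OLS(y, X).fit()
        self.coef_ = np.asarray(res.params)
        rss = float(res.ssr)
        self.degenerate_ = rss <= max(1e-12 * float(y @ y), 1e-300)
        self.sigma2_ = rss / n  # ML variance estimate
        self.loglik_ = np.inf if self.degenerate_ else float(res.llf)
        self.k_ = p + 1
        self.n_ = n
        return self

    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.coef_


class CMPRegression(BaseEstimator):
    """Mean-parameterized CMP regression with log link.

    Joint maximum likelihood over (coefficients, log nu) by quasi-Newton
    optimization, initialized from a Poisson GLM fit. ``fix_nu`` pins the
    dispersion (``fix_nu=1`` reduces to Poisson regression).

    Attributes after ``fit``: ``coef_``, ``nu_``, ``loglik_``, ``k_``, ``n_``.
    """

    def __init__(self, fix_nu: float | None = None, tol: float = 1e-9, max_iter: int = 500):
        self.fix_nu = fix_nu
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n, p = X.shape
        if np.any(y < 0) or np.any(y != np.floor(y)):
            raise ValidationError("counts must be non-negative integers")
        if n <= p:
            raise ValidationError(f"need n > k: n={n}, p={p}")
        if np.linalg.matrix_rank(X) < p:
            raise ValidationError("design matrix is rank-deficient")

        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        beta0 = np.asarray(pois.params)
        lgy = gammaln(y + 1.0)

        def negll(params):
            if self.fix_nu is None:
                beta, nu = params[:-1], float(np.exp(params[-1]))
            else:
                beta, nu = params, float(self.fix_nu)
            mu = np.exp(np.clip(X @ beta, -30.0, 30.0))
            try:
                lam = solve_lambda(mu, nu)
            except (ConvergenceError, ValidationError):
                return 1e12
            j = np.arange(_support_bound(np.atleast_1d(lam), nu) + 1, dtype=float)
            logz = logsumexp(_log_terms(lam, nu, j), axis=-1)
            ll = np.sum(y * np.log(lam) - nu * lgy - logz)
            return -ll if np.isfinite(ll) else 1e12

        x0 = beta0 if self.fix_nu is not None else np.append(beta0, 0.0)
        res = minimize(
            negll, x0, method="BFGS",
            options={"gtol": self.tol * max(1.0, n), "maxiter": self.max_iter},
        )
        if not res.success and np.linalg.norm(res.jac) > 1e-3 * n:
            # One Nelder-Mead polish before giving up.
            res = minimize(negll, res.x, method="Nelder-Mead",
                           options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 5000})
            if not res.success:
                raise ConvergenceError(
                    "CMP regression failed to converge",
                    diagnostics={"message": res.message, "x": res.x.tolist()},
                )
        if self.fix_nu is None:
            self.coef_ = res.x[:-1]
            self.nu_ = float(np.exp(res.x[-1]))
            self.k_ = p + 1
        else:
            self.coef_ = res.x
            self.nu_ = float(self.fix_nu)
            self.k_ = p  # pinned dispersion is not an estimated parameter
        self.loglik_ = -float(res.fun)
        self.n_ = n
        return self

    def predict(self, X):
        return np.exp(np.asarray(X, dtype=float) @ self.coef_)


def _names(X, names):
    p = X.shape[1] if X.ndim == 2 else 1
    if names is None:
        return [f"b{i}" for i in range(p)]
    if len(names) != p:
        raise ValidationError("names length does not match design columns")
    return list(names)


def fit_binomial(y, X, names=None) -> GlmFit:
    """Binomial-logit GLM via IRLS; returns a :class:`GlmFit`."""
    est = BinomialGLM().fit(X, y)
    return GlmFit(
        family="binomial-logit",
        params=dict(zip(_names(np.atleast_2d(X), names), est.coef_)),
        loglik=est.loglik_,
        k=est.k_,
        n=est.n_,
        extra={"separation": est.separation_},
    )


def fit_gaussian(y, X, names=None) -> GlmFit:
    """Gaussian identity-link model; full-ML log-likelihood, variance counted in k."""
    est = GaussianGLM().fit(X, y)
    return GlmFit(
        family="gaussian-identity",
        params=dict(zip(_names(np.atleast_2d(X), names), est.coef_)),
        loglik=est.loglik_,
        k=est.k_,
        n=est.n_,
        extra={"sigma2": est.sigma2_, "degenerate": est.degenerate_},
    )


def fit_cmp_regression(y, X, names=None, fix_nu: float | None = None) -> GlmFit:
    """Mean-parameterized CMP regression with log link; dispersion counted in k."""
    est = CMPRegression(fix_nu=fix_nu).fit(X, y)
    return GlmFit(
        family="cmp-log",
        params=dict(zip(_names(np.atleast_2d(X), names), est.coef_)),
        loglik=est.loglik_,
        k=est.k_,
        n=est.n_,
        extra={"nu": est.nu_},
    )


def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 loglik + 2k + 2k(k+1)/(n - k - 1)."""
    if n <= k + 1:
        raise ValidationError(f"AICc undefined for n <= k + 1 (n={n}, k={k})")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def rank_models(fits: dict[str, GlmFit]) -> pd.DataFrame:
    """AICc-ranked candidate model table with Akaike weights.

    All fits must be on the same observations. Rows are sorted by AICc,
    ties broken by smaller ``k`` then label; columns match the conventional
    Model / K / AICc / DeltaAICc / Weight / CumWeight layout.
    """
    if not fits:
        raise ValidationError("no models to rank")
    sizes = {f.n for f in fits.values()}
    if len(sizes) > 1:
        raise ValidationError(f"models fitted on different sample sizes: {sorted(sizes)}")
    rows = [(label, f.k, aicc(f.loglik, f.k, f.n)) for label, f in fits.items()]
    tab = pd.DataFrame(rows, columns=["Model", "K", "AICc"])
    tab = tab.sort_values(["AICc", "K", "Model"], kind="stable").reset_index(drop=True)
    tab["DeltaAICc"] = tab["AICc"] - tab["AICc"].iloc[0]
    w = np.exp(-0.5 * tab["DeltaAICc"].to_numpy())
    tab["Weight"] = w / w.sum()
    tab["CumWeight"] = tab["Weight"].cumsum()
    return tab


# ---------------------------------------------------------------------------
# Candidate sets (first-spring analyses)

_STATE_MODELS = {
    "Weight + Age + Weight x Age": ["weight_z", "age_adult", "weight_z:age_adult"],
    "Weight": ["weight_z"],
    "Intercept": [],
    "Age": ["age_adult"],
    "Weight + Age": ["weight_z", "age_adult"],
}

_NEST_MODELS = {
    "Intercept": [],
    "Age": ["age_adult"],
    "Weight": ["weight_z"],
    "Migratory strategy": ["migrant"],
    "Age + Weight": ["age_adult", "weight_z"],
    "Age + Migratory strategy": ["age_adult", "migrant"],
    "Migratory strategy + Weight": ["migrant", "weight_z"],
    "Migratory strategy + Age + Weight": ["migrant", "age_adult", "weight_z"],
}


def _design(df: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["(Intercept)"]
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            cols.append(df[a].to_numpy(dtype=float) * df[b].to_numpy(dtype=float))
        else:
            cols.append(df[t].to_numpy(dtype=float))
        names.append(t)
    return np.column_stack(cols), names


def _first_spring_frame(transitions: pd.DataFrame, birds: pd.DataFrame) -> pd.DataFrame:
    need = {"bird_id", "age_class", "weight_g"}
    if missing := need - set(birds.columns):
        raise ValidationError(f"birds table is missing columns: {sorted(missing)}")
    fs = transitions[transitions["is_first_spring"]].merge(
        birds[["bird_id", "age_class", "weight_g"]], on="bird_id", validate="one_to_one"
    )
    if len(fs) == 0:
        raise ValidationError("no first-spring transitions available")
    fs = fs.assign(
        migrant=(fs["strategy"] == "migrant").astype(float),
        age_adult=(fs["age_class"] == "adult").astype(float),
        weight_z=standardize(fs["weight_g"]),
        log_dist=np.log(fs["distance_m"].to_numpy(dtype=float) + 1.0),
    )
    return fs


def run_candidate_sets(
    transitions: pd.DataFrame,
    birds: pd.DataFrame,
    nests: pd.DataFrame | None = None,
) -> dict[str, dict]:
    """Fit and rank all four first-spring candidate sets.

    Returns a dict keyed by analysis name (``migration``, ``distance``,
    ``clutch``, ``nest_fate``), each holding ``table`` (the ranked model
    table) and ``fits`` (label → :class:`GlmFit`).
    """
    fs = _first_spring_frame(transitions, birds)
    out: dict[str, dict] = {}

    fits = {}
    for label, terms in _STATE_MODELS.items():
        X, names = _design(fs, terms)
        fits[label] = fit_binomial(fs["migrant"].to_numpy(), X, names)
    out["migration"] = {"table": rank_models(fits), "fits": fits}

    fits = {}
    for label, terms in _STATE_MODELS.items():
        X, names = _design(fs, terms)
        fits[label] = fit_gaussian(fs["log_dist"].to_numpy(), X, names)
    out["distance"] = {"table": rank_models(fits), "fits": fits}

    if nests is not None and len(nests):
        need = {"bird_id", "year", "clutch_size", "fate"}
        if missing := need - set(nests.columns):
            raise ValidationError(f"nests table is missing columns: {sorted(missing)}")
        nest_fs = nests.merge(
            fs[["bird_id", "to_year", "migrant", "age_adult", "weight_g"]],
            left_on=["bird_id", "year"],
            right_on=["bird_id", "to_year"],
            validate="one_to_one",
        )
        if len(nest_fs):
            nest_fs = nest_fs.assign(weight_z=standardize(nest_fs["weight_g"]))
            fits = {}
            for label, terms in _NEST_MODELS.items():
                X, names = _design(nest_fs, terms)
                fits[label] = fit_cmp_regression(nest_fs["clutch_size"].to_numpy(), X, names)
            out["clutch"] = {"table": rank_models(fits), "fits": fits}

            hatched = (nest_fs["fate"] == "hatched").astype(float).to_numpy()
            fits = {}
            for label, terms in _NEST_MODELS.items():
                X, names = _design(nest_fs, terms)
                fits[label] = fit_binomial(hatched, X, names)
            out["nest_fate"] = {"table": rank_models(fits), "fits": fits}
    return out
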