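"""Random-intercept mixed models of received level vs age class.

Received levels of calls are not independent draws: each individual
contributes many calls at its own characteristic level. The model is the
Gaussian random-intercept LMM

    rl_ij = x_ij' beta + b_i + e_ij,   b_i ~ N(0, sigma_b^2),
                                       e_ij ~ N(0, sigma_e^2),

with individual ``i`` as the grouping factor and age class (calf vs adult,
adult as reference) as the single fixed-effect contrast in the full model.
The likelihood is maximized by profiling: for a given variance ratio
``gamma = sigma_b^2 / sigma_e^2`` the fixed effects have a GLS closed form
and the residual variance a closed form, leaving a 1-D optimization over
``gamma`` (block-diagonal covariance, inverted analytically per group).
Support for age class is judged by comparing the full model against an
intercept-only null via AIC; ML is the default since REML likelihoods are
not comparable across fixed-effect structures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from .exceptions import ComparisonError, InvalidParameterError, RandomEffectError

__all__ = ["LmmFit", "RandomInterceptModel", "fit_random_intercept", "compare_aic"]


@dataclass
class LmmFit:
    beta: np.ndarray
    beta_names: list[str]
    sigma_b2: float
    sigma_e2: float
    log_lik: float
    aic: float
    n_params: int
    method: str
    n_obs: int


class RandomInterceptModel(BaseEstimator):
    """Gaussian random-intercept model fitted by profiled (RE)ML.

    Parameters
    ----------
    formula : "age_class" (intercept + calf contrast) or "intercept_only".
    method : "ML" (default, AIC-comparable across formulas) or "REML".
    reference : reference level of the age-class contrast.

    Fitted attributes: ``beta_`` (fixed effects, dB), ``sigma_b2_``
    (between-individual variance, dB^2), ``sigma_e2_`` (residual variance,
    dB^2), ``log_lik_``, ``aic_``, ``n_params_``, ``gamma_``.
    """

    def __init__(self, formula: str = "age_class", method: str = "ML",
                 reference: str = "adult"):
        self.formula = formula
        self.method = method
        self.reference = reference

    # -- design ------------------------------------------------------------
    def _design(self, data: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        n = len(data)
        if self.formula == "intercept_only":
            return np.ones((n, 1)), ["(Intercept)"]
        if self.formula == "age_class":
            contrast = (data["age_class"] != self.reference).to_numpy(dtype=float)
            levels = sorted(set(data["age_class"]) - {self.reference})
            name = f"age_class[{levels[0]}]" if levels else "age_class[.]"
            return np.column_stack([np.ones(n), contrast]), ["(Intercept)", name]
        raise InvalidParameterError(f"unknown formula {self.formula!r}")

    def fit(self, data: pd.DataFrame, y_col: str = "rl_db",
            group_col: str = "caller_id"):
        data = data.dropna(subset=[y_col]).reset_index(drop=True)
        y = data[y_col].to_numpy(dtype=float)
        groups = data[group_col].astype(str).to_numpy()
        if len(np.unique(groups)) < 2:
            raise RandomEffectError(
                "random intercept is inestimable with a single individual"
            )
        X, names = self._design(data)
        if self.method not in ("ML", "REML"):
            raise InvalidParameterError("method must be ML or REML")
        reml = self.method == "REML"
        idx = [np.flatnonzero(groups == g) for g in np.unique(groups)]

        def profile_nll(log_gamma: float) -> float:
            return -_profile_loglik(np.exp(log_gamma), y, X, idx, reml)[0]

        res = minimize_scalar(profile_nll, bounds=(-18.0, 12.0), method="bounded",
                              options={"xatol": 1e-10})
        at_gamma = _profile_loglik(np.exp(res.x), y, X, idx, reml)
        at_zero = _profile_loglik(0.0, y, X, idx, reml)
        if at_zero[0] >= at_gamma[0]:  # boundary: no between-individual variance
            gamma, (ll, beta, sigma_e2) = 0.0, at_zero
        else:
            gamma, (ll, beta, sigma_e2) = float(np.exp(res.x)), at_gamma
        self.gamma_ = gamma
        self.beta_ = beta
        self.beta_names_ = names
        self.sigma_e2_ = sigma_e2
        self.sigma_b2_ = gamma * sigma_e2
        self.log_lik_ = ll
        self.n_params_ = X.shape[1] + 2
        self.aic_ = -2.0 * ll + 2.0 * self.n_params_
        self.n_obs_ = len(y)
        self._fingerprint = (len(y), float(np.sum(y)), float(np.sum(y**2)))
        return self

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Population-level (fixed-effects) prediction."""
        X, _ = self._design(data)
        return X @ self.beta_

    def to_fit(self) -> LmmFit:
        return LmmFit(
            beta=self.beta_, beta_names=self.beta_names_,
            sigma_b2=self.sigma_b2_, sigma_e2=self.sigma_e2_,
            log_lik=self.log_lik_, aic=self.aic_, n_params=self.n_params_,
            method=self.method, n_obs=self.n_obs_,
        )


def _profile_loglik(
    gamma: float, y: np.ndarray, X: np.ndarray, idx: list[np.ndarray], reml: bool
) -> tuple[float, np.ndarray, float]:
    """Profiled log-likelihood at variance ratio ``gamma``.

    V_i = I + gamma J has analytic inverse I - (gamma / (1 + gamma n_i)) J
    and log-determinant log(1 + gamma n_i); beta and sigma_e^2 are profiled
    out in closed form. Returns (log_lik, beta, sigma_e2).
    """
    n, p = X.shape
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    logdet = 0.0
    for rows in idx:
        ni = len(rows)
        shrink = gamma / (1.0 + gamma * ni)
        Xi, yi = X[rows], y[rows]
        sx, sy = Xi.sum(axis=0), yi.sum()
        XtVX += Xi.T @ Xi - shrink * np.outer(sx, sx)
        XtVy += Xi.T @ yi - shrink * sx * sy
        logdet += np.log1p(gamma * ni)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = 0.0
    for rows in idx:
        ni = len(rows)
        shrink = gamma / (1.0 + gamma * ni)
        r = y[rows] - X[rows] @ beta
        rss += r @ r - shrink * r.sum() ** 2
    if reml:
        dof = n - p
        sigma_e2 = rss / dof
        sign, logdet_xvx = np.linalg.slogdet(XtVX)
        ll = -0.5 * (
            dof * np.log(2 * np.pi * sigma_e2) + logdet + logdet_xvx + dof
        )
    else:
        sigma_e2 = rss / n
        ll = -0.5 * (n * np.log(2 * np.pi * sigma_e2) + logdet + n)
    return float(ll), beta, float(sigma_e2)


def fit_random_intercept(
    data: pd.DataFrame,
    fixed_formula: str = "age_class",
    method: str = "ML",
    y_col: str = "rl_db",
    group_col: str = "caller_id",
) -> LmmFit:
    """Fit the random-intercept model and return its summary."""
    model = RandomInterceptModel(formula=fixed_formula, method=method)
    return model.fit(data, y_col=y_col, group_col=group_col).to_fit()


def compare_aic(full: RandomInterceptModel | LmmFit,
                null: RandomInterceptModel | LmmFit) -> float:
    """AIC(full) - AIC(null); positive means the null model is preferred."""
    f_aic, f_meta = _aic_meta(full)
    n_aic, n_meta = _aic_meta(null)
    if f_meta != n_meta:
        raise ComparisonError(
            "models were fitted on different data or with different methods"
        )
    return float(f_aic - n_aic)


def _aic_meta(fit) -> tuple[float, tuple]:
    if isinstance(fit, RandomInterceptModel):
        return fit.aic_, (fit.method,) + fit._fingerprint
    return fit.aic, (fit.method, fit.n_obs)
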