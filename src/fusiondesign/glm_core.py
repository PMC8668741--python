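"""Negative-binomial and binomial GLMs with offsets, fitted by IRLS.

Model objects follow the statsmodels convention: construct from data, call
``fit()``, get a :class:`GLMResults` carrying coefficients, covariance,
dispersion, log-likelihood and a ``summary()`` table.

Parameterization
----------------
The negative binomial uses the ecology convention ``Var(Y) = mu + mu^2 / theta``
(small theta = strong overdispersion). The log-likelihood is evaluated with
gamma functions, so non-integer responses — corrected carcass counts — are
admissible::

    ll_i = lgamma(y_i + theta) - lgamma(theta) - lgamma(y_i + 1)
           + theta * log(theta / (theta + mu_i)) + y_i * log(mu_i / (theta + mu_i))

``theta`` is estimated by profile maximum likelihood: IRLS for the
coefficients at fixed theta, alternated with a one-dimensional maximization
of the profile likelihood in log(theta), until both have converged
(coefficients to 1e-8 max-norm, theta to 1e-6 relative). Near-Poisson data
push theta to the cap ``THETA_MAX``; the fit is then reported at the cap,
which is numerically indistinguishable from Poisson.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "GLMResults",
    "NegativeBinomialModel",
    "BinomialModel",
    "WaldResult",
    "wald_inference",
    "cyclic_spline_basis",
    "THETA_MAX",
    "THETA_MIN",
]

THETA_MIN = 1e-4
THETA_MAX = 1e7

_ETA_CLIP = 30.0  # exp(30) ~ 1e13; keeps IRLS finite on wild starting values


class WaldResult(NamedTuple):
    estimate: float
    se: float
    z: float
    p_value: float
    ci_low: float
    ci_high: float


def _as_design(exog) -> tuple[np.ndarray, list[str]]:
    if isinstance(exog, pd.DataFrame):
        return np.asarray(exog, dtype=float), [str(c) for c in exog.columns]
    X = np.atleast_2d(np.asarray(exog, dtype=float))
    return X, [f"x{i}" for i in range(X.shape[1])]


@dataclass
class GLMResults:
    """Fit results: estimates, uncertainty, dispersion and diagnostics."""

    params: pd.Series
    cov_params: pd.DataFrame
    theta: float | None
    llf: float
    converged: bool
    n_iter: int
    fittedvalues: np.ndarray
    resid_response: np.ndarray
    family: str
    nobs: int
    diagnostic: str = ""

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.params.index)

    def wald(self, name: str, level: float = 0.95) -> WaldResult:
        return wald_inference(self, name, level)

    def summary(self) -> str:
        lines = [
            f"{self.family} GLM  (nobs={self.nobs}, llf={self.llf:.4f}, "
            f"converged={self.converged}, iterations={self.n_iter})",
        ]
        if self.theta is not None:
            lines[0] += f"  theta={self.theta:.4g}"
        lines.append(f"{'term':<20}{'coef':>12}{'se':>12}{'z':>9}{'P>|z|':>10}")
        bse = self.bse
        for name, beta in self.params.items():
            se = bse[name]
            z = beta / se if se > 0 else np.nan
            p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            lines.append(f"{name:<20}{beta:>12.4f}{se:>12.4f}{z:>9.2f}{p:>10.4g}")
        if self.diagnostic:
            lines.append(f"note: {self.diagnostic}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        bse = self.bse
        return {
            "family": self.family,
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "standard_errors": {k: float(bse[k]) for k in self.params.index},
            "p_values": {
                k: float(2 * stats.norm.sf(abs(v / bse[k]))) if bse[k] > 0 else None
                for k, v in self.params.items()
            },
            "theta": None if self.theta is None else float(self.theta),
            "log_likelihood": float(self.llf),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def wald_inference(fit: GLMResults, coefficient_name: str, level: float = 0.95) -> WaldResult:
    """Wald estimate, SE, z, two-sided p and CI for one coefficient (link scale)."""
    if coefficient_name not in fit.params.index:
        raise KeyError(f"no coefficient {coefficient_name!r}; have {list(fit.params.index)}")
    beta = float(fit.params[coefficient_name])
    se = float(fit.bse[coefficient_name])
    if not np.isfinite(se) or se <= 0:
        raise ValueError(f"degenerate variance for {coefficient_name!r} (se={se})")
    z = beta / se
    p = float(2 * stats.norm.sf(abs(z)))
    q = stats.norm.ppf(1 - (1 - level) / 2)
    return WaldResult(beta, se, z, p, beta - q * se, beta + q * se)


# ---------------------------------------------------------------------------
# negative binomial
# ---------------------------------------------------------------------------

def _nb_loglike(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    mu = np.clip(mu, 1e-12, None)
    return float(np.sum(
        special.gammaln(y + theta) - special.gammaln(theta) - special.gammaln(y + 1.0)
        + theta * np.log(theta / (theta + mu)) + y * np.log(mu / (theta + mu))
    ))


def _irls_nb(y, X, offset, theta, beta0, tol, maxiter):
    """IRLS for fixed theta with step-halving so the likelihood never drops."""
    beta = beta0.copy()
    eta = np.clip(X @ beta + offset, -_ETA_CLIP, _ETA_CLIP)
    ll = _nb_loglike(y, np.exp(eta), theta)
    converged = False
    it = 0
    for it in range(1, maxiter + 1):
        mu = np.exp(eta)
        w = mu / (1.0 + mu / theta)
        z = (eta - offset) + (y - mu) / mu
        XtW = X.T * w
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(XtW @ X, XtW @ z, rcond=None)[0]
        step = beta_new - beta
        # step-halve if the proposal meaningfully lowers the likelihood;
        # the slack absorbs gammaln round-off at extreme theta
        slack = 1e-9 * (1.0 + abs(ll))
        for _ in range(25):
            eta_try = np.clip(X @ (beta + step) + offset, -_ETA_CLIP, _ETA_CLIP)
            ll_try = _nb_loglike(y, np.exp(eta_try), theta)
            if ll_try >= ll - slack:
                break
            step *= 0.5
        beta = beta + step
        eta = np.clip(X @ beta + offset, -_ETA_CLIP, _ETA_CLIP)
        ll_new = _nb_loglike(y, np.exp(eta), theta)
        delta = np.max(np.abs(step))
        ll = ll_new
        if delta < tol:
            converged = True
            break
    return beta, eta, ll, converged, it


def _profile_theta(y, mu, theta0):
    """Maximize the NB log-likelihood over theta at fixed mean vector."""
    def nll(log_theta):
        return -_nb_loglike(y, mu, math.exp(log_theta))
    res = optimize.minimize_scalar(
        nll, bounds=(math.log(THETA_MIN), math.log(THETA_MAX)), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(math.exp(res.x))


class NegativeBinomialModel:
    """Log-link negative-binomial regression with offset.

    Parameters
    ----------
    endog : array-like of non-negative reals
        Response; non-integer values (corrected counts) are allowed.
    exog : DataFrame or 2-D array
        Design matrix including the intercept column.
    offset : array-like, optional
        Log-scale offset (coefficient fixed at 1); zeros if absent.
    """

    def __init__(self, endog, exog, offset=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog, self.exog_names = _as_design(exog)
        self.offset = (np.zeros(len(self.endog)) if offset is None
                       else np.asarray(offset, dtype=float))
        if self.endog.ndim != 1:
            raise ValueError("endog must be one-dimensional")
        if np.any(self.endog < 0):
            raise ValueError("negative binomial response must be non-negative")
        if len(self.endog) != self.exog.shape[0] or len(self.endog) != len(self.offset):
            raise ValueError("endog, exog and offset lengths differ")
        if np.all(self.endog == 0):
            raise ValueError("all-zero response: negative binomial model unidentifiable")
        if np.linalg.matrix_rank(self.exog) < self.exog.shape[1]:
            raise ValueError("design matrix is rank deficient")

    def loglike(self, params, theta: float) -> float:
        eta = self.exog @ np.asarray(params, dtype=float) + self.offset
        return _nb_loglike(self.endog, np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP)), theta)

    def fit(self, theta: float | None = None, tol: float = 1e-8,
            theta_tol: float = 1e-6, maxiter: int = 100) -> GLMResults:
        """Fit by IRLS; ``theta=None`` profiles the dispersion jointly."""
        y, X, offset = self.endog, self.exog, self.offset
        mu0 = np.clip((y + np.mean(y)) / 2.0, 1e-3, None)
        eta0 = np.log(mu0) - offset
        beta = np.linalg.lstsq(X, eta0, rcond=None)[0]

        fixed_theta = theta is not None
        if fixed_theta:
            th = float(theta)
            if not th > 0:
                raise ValueError("theta must be positive")
        else:
            # method-of-moments initializer from the crude start
            mu = np.exp(np.clip(X @ beta + offset, -_ETA_CLIP, _ETA_CLIP))
            excess = np.sum((y - mu) ** 2 - mu)
            th = float(np.clip(np.sum(mu ** 2) / excess if excess > 0 else THETA_MAX,
                               THETA_MIN, THETA_MAX))

        converged = False
        total_iter = 0
        ll = -np.inf
        if fixed_theta:
            beta, eta, ll, converged, total_iter = _irls_nb(
                y, X, offset, th, beta, tol, maxiter)
        else:
            eta = np.clip(X @ beta + offset, -_ETA_CLIP, _ETA_CLIP)
            for _ in range(50):
                # update theta on the current mean, then re-converge the
                # coefficients at that theta, so the returned beta always
                # belongs to the returned theta
                th_new = _profile_theta(y, np.exp(eta), th)
                if th_new > THETA_MAX / 10:
                    # profile likelihood is flat in the Poisson limit; pin to the cap
                    th_new = THETA_MAX
                rel = abs(th_new - th) / max(1.0, th)
                ll_at_new = _nb_loglike(y, np.exp(eta), th_new)
                dll = ll_at_new - ll if np.isfinite(ll) else np.inf
                th = th_new
                beta, eta, ll, beta_conv, it = _irls_nb(
                    y, X, offset, th, beta, tol, maxiter)
                total_iter += it
                if beta_conv and (rel < theta_tol or abs(dll) < 1e-8):
                    converged = True
                    break

        mu = np.exp(np.clip(X @ beta + offset, -_ETA_CLIP, _ETA_CLIP))
        w = mu / (1.0 + mu / th)
        cov = np.linalg.pinv((X.T * w) @ X)
        diag = "" if converged else "maximum iterations reached without convergence"
        at_cap = not fixed_theta and th >= THETA_MAX * (1 - 1e-9)
        if at_cap:
            diag = (diag + "; " if diag else "") + "theta at upper bound (Poisson limit)"
        return GLMResults(
            params=pd.Series(beta, index=self.exog_names),
            cov_params=pd.DataFrame(cov, index=self.exog_names, columns=self.exog_names),
            theta=th, llf=ll, converged=converged, n_iter=total_iter,
            fittedvalues=mu, resid_response=y - mu,
            family="NegativeBinomial", nobs=len(y), diagnostic=diag,
        )


# ---------------------------------------------------------------------------
# binomial
# ---------------------------------------------------------------------------

def _binom_loglike(events, trials, p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(
        special.gammaln(trials + 1) - special.gammaln(events + 1)
        - special.gammaln(trials - events + 1)
        + events * np.log(p) + (trials - events) * np.log1p(-p)
    ))


class BinomialModel:
    """Logit-link binomial regression on (events, non-events) pairs."""

    def __init__(self, events, nonevents, exog, offset=None):
        self.events = np.asarray(events, dtype=float)
        self.nonevents = np.asarray(nonevents, dtype=float)
        self.exog, self.exog_names = _as_design(exog)
        self.offset = (np.zeros(len(self.events)) if offset is None
                       else np.asarray(offset, dtype=float))
        if np.any(self.events < 0) or np.any(self.nonevents < 0):
            raise ValueError("event and non-event counts must be non-negative")
        if np.any(self.events + self.nonevents <= 0):
            raise ValueError("each row needs events + nonevents > 0")
        if np.any(self.events != np.round(self.events)) or np.any(
                self.nonevents != np.round(self.nonevents)):
            raise ValueError("binomial responses must be integers")

    @property
    def trials(self) -> np.ndarray:
        return self.events + self.nonevents

    def loglike(self, params) -> float:
        eta = np.clip(self.exog @ np.asarray(params, dtype=float) + self.offset,
                      -_ETA_CLIP, _ETA_CLIP)
        return _binom_loglike(self.events, self.trials, special.expit(eta))

    def fit(self, tol: float = 1e-8, maxiter: int = 100) -> GLMResults:
        k, n, X, offset = self.events, self.trials, self.exog, self.offset
        p0 = (k + 0.5) / (n + 1.0)
        beta = np.linalg.lstsq(X, special.logit(p0) - offset, rcond=None)[0]
        ll = self.loglike(beta)
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            eta = np.clip(X @ beta + offset, -_ETA_CLIP, _ETA_CLIP)
            p = special.expit(eta)
            w = n * p * (1 - p)
            w = np.clip(w, 1e-12, None)
            z = (eta - offset) + (k - n * p) / w
            XtW = X.T * w
            try:
                beta_new = np.linalg.solve(XtW @ X, XtW @ z)
            except np.linalg.LinAlgError:
                beta_new = np.linalg.lstsq(XtW @ X, XtW @ z, rcond=None)[0]
            step = beta_new - beta
            for _ in range(25):
                if self.loglike(beta + step) >= ll - 1e-12:
                    break
                step *= 0.5
            beta = beta + step
            ll = self.loglike(beta)
            if np.max(np.abs(step)) < tol:
                converged = True
                break
        eta = np.clip(X @ beta + offset, -_ETA_CLIP, _ETA_CLIP)
        p = special.expit(eta)
        w = np.clip(n * p * (1 - p), 1e-12, None)
        cov = np.linalg.pinv((X.T * w) @ X)
        diag = ""
        if not converged:
            diag = "maximum iterations reached without convergence"
        if np.max(np.abs(X @ beta + offset)) >= _ETA_CLIP - 1e-6:
            # fitted probabilities pinned at 0/1: the MLE is at infinity
            converged = False
            diag = (diag + "; " if diag else "") + \
                "fitted probabilities at boundary (possible complete separation)"
        return GLMResults(
            params=pd.Series(beta, index=self.exog_names),
            cov_params=pd.DataFrame(cov, index=self.exog_names, columns=self.exog_names),
            theta=None, llf=ll, converged=converged, n_iter=it,
            fittedvalues=n * p, resid_response=k - n * p,
            family="Binomial", nobs=len(k), diagnostic=diag,
        )


# ---------------------------------------------------------------------------
# cyclic spline basis
# ---------------------------------------------------------------------------

def cyclic_spline_basis(jday, n_basis: int = 8, period: float = 366.0,
                        center: bool = True) -> np.ndarray:
    """Cyclic cubic B-spline basis on day-of-year [1, 1 + period).

    Knots are equally spaced over the period and the basis wraps around the
    seam, so value, first and second derivatives match between day 366 and
    day 1. The uncentered basis is a partition of unity (rows sum to 1) and
    therefore collinear with an intercept; with ``center=True`` one column
    is dropped and the rest are centered on a fine within-period grid,
    giving ``n_basis - 1`` columns safe to combine with an intercept.
    """
    if n_basis < 3:
        raise ValueError("n_basis must be at least 3")
    from scipy.interpolate import BSpline

    degree = 3
    x = 1.0 + np.mod(np.asarray(jday, dtype=float) - 1.0, period)

    def raw(xv: np.ndarray) -> np.ndarray:
        knots = np.linspace(1.0, 1.0 + period, n_basis + 1)
        t = np.concatenate([knots[-degree - 1:-1] - period, knots,
                            knots[1:degree + 1] + period])
        design = BSpline.design_matrix(xv, t, degree, extrapolate=False).toarray()
        folded = design[:, :n_basis].copy()
        folded[:, :degree] += design[:, n_basis:n_basis + degree]
        return folded

    B = raw(x)
    if not center:
        return B
    grid = 1.0 + np.arange(math.ceil(period)) % period
    means = raw(grid).mean(axis=0)
    return (B - means)[:, : n_basis - 1]
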