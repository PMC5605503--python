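"""Statistical analysis of trial-by-trial detection accuracy.

The core model is a random-intercept logistic regression: for participant i
on trial j,

    logit P(correct_ij = 1) = x_ij' beta + u_i,   u_i ~ Normal(0, sigma_u^2)

with fixed effects for Group, Age, Trial type, Subtlety, the two condition
dummies and Group × Subtlety. The marginal likelihood integrates the random
intercept out with adaptive Gauss–Hermite quadrature (the integrand is
re-centered at each participant's posterior mode, so order 1 recovers the
Laplace approximation); it is maximized over (beta, sigma_u) and standard
errors come from the observed information of the marginal log-likelihood.
Coefficients are tested with Wald Z statistics.

Signal-detection and accuracy summaries per (group, condition, subtlety)
cell complete the analysis; with only a handful of chase-absent trials per
cell the raw false-alarm rate is often 0, so d' supports the log-linear and
half-count corrections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

import statsmodels.api as sm

from .exceptions import (
    InvalidParameterError,
    NotConvergedError,
    SeparationError,
    UndefinedFAError,
)

__all__ = [
    "GlmmFit",
    "DEFAULT_TERMS",
    "fit_random_intercept_logistic",
    "wald_table",
    "dprime_table",
    "accuracy_summary",
]

#: Fixed-effect terms of the final accuracy model, in reporting order.
DEFAULT_TERMS = (
    "intercept", "group", "age", "trial_type",
    "subtlety", "social", "nonsocial", "group_x_subtlety",
)

_CI_Z = 1.96  # normal quantile used for the reported 95% intervals


@dataclass
class GlmmFit:
    """Result of a random-intercept logistic fit."""

    fixed_effects: pd.DataFrame  # index = term; estimate, se, z, p, ci_low, ci_high
    sigma_u_hat: float
    log_likelihood: float
    converged: bool
    n_obs: int
    n_participants: int
    quad_order: int
    message: str = ""

    def estimate(self, term: str) -> float:
        return float(self.fixed_effects.loc[term, "estimate"])


def _design_matrix(responses: pd.DataFrame, terms: tuple[str, ...]) -> np.ndarray:
    cols = {
        "intercept": np.ones(len(responses)),
        "group": responses["group"].to_numpy(float),
        "age": responses["age"].to_numpy(float),
        "trial_type": responses["chase_present"].to_numpy(float),
        "subtlety": responses["subtlety"].to_numpy(float),
        "social": (responses["condition"] == "social").to_numpy(float),
        "nonsocial": (responses["condition"] == "nonsocial").to_numpy(float),
        "group_x_subtlety": (
            responses["group"].to_numpy(float)
            * responses["subtlety"].to_numpy(float)
        ),
    }
    try:
        return np.column_stack([cols[t] for t in terms])
    except KeyError as err:  # pragma: no cover - user error path
        raise InvalidParameterError(f"unknown model term {err}") from None


class _MarginalLikelihood:
    """Marginal log-likelihood of the random-intercept logit, evaluated with
    adaptive Gauss–Hermite quadrature (observations pre-sorted by group)."""

    def __init__(self, X: np.ndarray, y: np.ndarray, gidx: np.ndarray, order: int):
        sort = np.argsort(gidx, kind="stable")
        self.X = X[sort]
        self.y = y[sort].astype(float)
        g = gidx[sort]
        self.starts = np.concatenate(([0], np.flatnonzero(np.diff(g)) + 1))
        self.gidx = np.searchsorted(self.starts, np.arange(len(g)), side="right") - 1
        self.n_groups = len(self.starts)
        nodes, weights = np.polynomial.hermite.hermgauss(order)
        self.nodes = nodes
        self.logw = np.log(weights) + nodes**2
        self._zwarm = np.zeros(self.n_groups)

    def _group_sum(self, arr: np.ndarray) -> np.ndarray:
        return np.add.reduceat(arr, self.starts, axis=0)

    def _modes(self, eta0: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
        """Per-group posterior mode and curvature of the random intercept."""
        # The per-group posterior in z is strictly concave, so a step-clipped
        # Newton iteration converges from any start; the warm start from the
        # previous evaluation usually leaves only 2-3 iterations.
        z = self._zwarm.copy()
        converged = False
        for _ in range(100):
            mu = expit(eta0 + sigma * z[self.gidx])
            grad = sigma * self._group_sum(self.y - mu) - z
            hess = -(sigma**2) * self._group_sum(mu * (1.0 - mu)) - 1.0
            step = np.clip(grad / hess, -2.0, 2.0)
            z -= step
            if np.max(np.abs(step)) < 1e-13:
                converged = True
                break
        if converged and np.all(np.isfinite(z)):
            self._zwarm = z.copy()
        else:  # pragma: no cover - extreme trial points only
            self._zwarm = np.zeros(self.n_groups)
        mu = expit(eta0 + sigma * z[self.gidx])
        curv = (sigma**2) * self._group_sum(mu * (1.0 - mu)) + 1.0
        return z, curv

    def loglik(self, beta: np.ndarray, sigma: float) -> float:
        eta0 = self.X @ beta
        base = self.y * eta0 - np.logaddexp(0.0, eta0)
        if sigma < 1e-10:
            return float(base.sum())
        zhat, curv = self._modes(eta0, sigma)
        tau = 1.0 / np.sqrt(curv)
        Z = zhat[:, None] + np.sqrt(2.0) * tau[:, None] * self.nodes[None, :]
        eta = eta0[:, None] + sigma * Z[self.gidx, :]
        ll = self.y[:, None] * eta - np.logaddexp(0.0, eta)
        h = self._group_sum(ll) - 0.5 * Z**2 - 0.5 * np.log(2.0 * np.pi)
        s = self.logw[None, :] + h
        smax = s.max(axis=1)
        lse = smax + np.log(np.exp(s - smax[:, None]).sum(axis=1))
        return float(np.sum(lse + 0.5 * np.log(2.0) + np.log(tau)))


def _numerical_hessian(f, x: np.ndarray, lower_bounds: np.ndarray) -> np.ndarray:
    """Central-difference Hessian, switching to forward differences where a
    lower bound is within reach of the step."""
    p = len(x)
    h = 1e-4 * (1.0 + np.abs(x))
    # keep evaluation points feasible
    shift = np.maximum(lower_bounds + 2.0 * h - x, 0.0)
    x0 = x + shift
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            fpp = f(x0 + ei + ej)
            fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej)
            fmm = f(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def fit_random_intercept_logistic(
    responses: pd.DataFrame,
    terms: tuple[str, ...] = DEFAULT_TERMS,
    quad_order: int = 9,
    compute_se: bool = True,
) -> GlmmFit:
    """Fit the random-intercept logistic accuracy model by marginal ML.

    ``responses`` needs columns ``participant_id``, ``correct`` and whatever
    covariates the requested ``terms`` use. ``quad_order`` sets the adaptive
    Gauss–Hermite order (1 = Laplace). Raises
    :class:`~chasedot.exceptions.SeparationError` on complete separation;
    non-convergence is flagged on the returned fit rather than raised.
    """
    ids = responses["participant_id"].to_numpy()
    uniq, gidx = np.unique(ids, return_inverse=True)
    if len(uniq) < 2:
        raise InvalidParameterError("need at least 2 participants")
    y = responses["correct"].to_numpy(float)
    X = _design_matrix(responses, terms)

    # fixed-effects-only fit: start values and separation screen
    try:
        start = sm.Logit(y, X).fit(disp=False, maxiter=200)
        beta0 = np.asarray(start.params)
    except Exception as err:
        raise SeparationError(f"fixed-effects logistic fit failed: {err}") from err
    mu0 = expit(X @ beta0)
    if np.max(np.abs(beta0)) > 1e3 or np.all(np.abs(y - mu0) < 1e-8):
        raise SeparationError("complete separation in the fixed-effects fit")

    # optimize on standardized columns: the raw covariates span three orders
    # of magnitude (subtlety in degrees vs dummies), which would leave the
    # finite-difference gradients badly conditioned
    scale = X.std(axis=0)
    scale[scale == 0.0] = 1.0
    Xs = X / scale
    ml = _MarginalLikelihood(Xs, y, gidx, quad_order)

    def nll(theta: np.ndarray) -> float:
        return -ml.loglik(theta[:-1], theta[-1])

    x0 = np.concatenate([beta0 * scale, [0.5]])
    bounds = [(None, None)] * X.shape[1] + [(0.0, None)]
    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7,
                                     "eps": 1e-7})
    theta = res.x
    sigma = float(theta[-1])
    if sigma < 1e-6:
        # boundary solution: the profile at sigma = 0 is exactly the plain
        # logistic model, whose own optimizer is the sharper one
        sigma = 0.0
        theta = np.concatenate([beta0 * scale, [0.0]])
    beta = theta[:-1] / scale
    loglik = float(ml.loglik(theta[:-1], sigma))

    se = np.full(len(theta), np.nan)
    if compute_se:
        lower = np.array([-np.inf] * X.shape[1] + [0.0])
        if sigma < 1e-6:
            # boundary: sigma pinned at 0, beta block from the plain logistic
            cov = np.asarray(start.cov_params())
            se[:-1] = np.sqrt(np.diag(cov))
            se[-1] = np.nan
        else:
            H = _numerical_hessian(nll, theta, lower)
            try:
                cov = np.linalg.inv(H)
                diag = np.diag(cov)
                if np.all(diag > 0):
                    se = np.sqrt(diag)
                    se[:-1] = se[:-1] / scale  # back to raw covariate units
            except np.linalg.LinAlgError:  # pragma: no cover
                pass

    est = pd.DataFrame(index=list(terms))
    est["estimate"] = beta
    est["se"] = se[:-1]
    est["z"] = est["estimate"] / est["se"]
    est["p"] = 2.0 * stats.norm.sf(np.abs(est["z"]))
    est["ci_low"] = est["estimate"] - _CI_Z * est["se"]
    est["ci_high"] = est["estimate"] + _CI_Z * est["se"]

    return GlmmFit(
        fixed_effects=est,
        sigma_u_hat=sigma,
        log_likelihood=loglik,
        converged=bool(res.success),
        n_obs=len(y),
        n_participants=len(uniq),
        quad_order=quad_order,
        message=str(res.message),
    )


def wald_table(fit: GlmmFit) -> pd.DataFrame:
    """Coefficient table with Wald Z tests, formatted in the reporting style
    of the study (p-values below 0.001 shown as "<0.001")."""
    if not fit.converged:
        raise NotConvergedError(
            f"refusing to tabulate an unconverged fit: {fit.message}"
        )
    tab = fit.fixed_effects.copy()
    tab["p_formatted"] = [
        "<0.001" if p < 0.001 else f"{p:.3f}" for p in tab["p"]
    ]
    return tab


def _rate(k: np.ndarray, n: np.ndarray, correction: str) -> np.ndarray:
    if correction == "none":
        return k / n
    if correction == "loglinear":
        return (k + 0.5) / (n + 1.0)
    if correction == "half_count":
        r = k / n
        r = np.where(r == 0.0, 1.0 / (2.0 * n), r)
        r = np.where(r == 1.0, 1.0 - 1.0 / (2.0 * n), r)
        return r
    raise InvalidParameterError(f"unknown correction {correction!r}")


_CELL = ["group", "condition", "subtlety"]


def dprime_table(responses: pd.DataFrame, correction: str = "loglinear") -> pd.DataFrame:
    """Per-cell signal-detection summary.

    Hit and false-alarm rates are computed per participant per (group,
    condition, subtlety) cell, corrected as requested, transformed with the
    normal quantile (d' = z(H) − z(FA)) and then averaged over participants.
    The returned frame also carries mean accuracy and its SEM.
    """
    per = []
    for (pid, *cell), sub in responses.groupby(["participant_id"] + _CELL,
                                               observed=True):
        present = sub[sub["chase_present"]]
        absent = sub[~sub["chase_present"]]
        if len(absent) == 0:
            raise UndefinedFAError(
                f"cell {tuple(cell)} for participant {pid} has no chase-absent trials"
            )
        per.append((pid, *cell, len(present),
                    int(present["response_present"].sum()),
                    len(absent), int(absent["response_present"].sum()),
                    float(sub["correct"].mean())))
    cols = ["participant_id", *_CELL, "n_present", "hits", "n_absent", "fas",
            "accuracy"]
    per = pd.DataFrame(per, columns=cols)
    H = _rate(per["hits"].to_numpy(float), per["n_present"].to_numpy(float), correction)
    FA = _rate(per["fas"].to_numpy(float), per["n_absent"].to_numpy(float), correction)
    per["hit_rate"] = H
    per["fa_rate"] = FA
    per["dprime"] = stats.norm.ppf(H) - stats.norm.ppf(FA)

    def _sem(x: pd.Series) -> float:
        return 0.0 if len(x) < 2 else float(x.std(ddof=1) / np.sqrt(len(x)))

    out = per.groupby(_CELL, observed=True).agg(
        hit_rate=("hit_rate", "mean"),
        fa_rate=("fa_rate", "mean"),
        dprime=("dprime", "mean"),
        mean_accuracy=("accuracy", "mean"),
        sem=("accuracy", _sem),
        n_participants=("participant_id", "nunique"),
    ).reset_index()
    return out


def accuracy_summary(responses: pd.DataFrame) -> pd.DataFrame:
    """Mean accuracy and SEM per (group, condition, subtlety) cell, with the
    participant as the unit of analysis (SEM = SD/sqrt(n); defined as 0 and
    flagged via ``n_participants`` when a cell holds a single participant)."""
    per = (
        responses.groupby(["participant_id"] + _CELL, observed=True)["correct"]
        .mean()
        .reset_index(name="accuracy")
    )

    def _sem(x: pd.Series) -> float:
        return 0.0 if len(x) < 2 else float(x.std(ddof=1) / np.sqrt(len(x)))

    out = per.groupby(_CELL, observed=True).agg(
        mean_accuracy=("accuracy", "mean"),
        sem=("accuracy", _sem),
        n_participants=("participant_id", "nunique"),
    ).reset_index()
    return out
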