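"""Single-grouping-factor random-intercept linear mixed model.

Per feature the model is

    y_ij = beta_0 + u_i + sum_k beta_k x_ik + e_ij,
    u_i ~ N(0, sigma_u^2),   e_ij ~ N(0, sigma_e^2),

with one random intercept per subject. Estimation profiles the fixed effects
and the residual variance out of the (restricted) likelihood, leaving a
one-dimensional problem in theta = sigma_u / sigma_e. With
V(theta) = I + theta^2 Z Z^T and Z the subject indicator matrix, V is
block-diagonal with blocks I + theta^2 J, so V^{-1} and log|V| have closed
forms per subject:

    V_g^{-1} = I - w_g J,   w_g = theta^2 / (1 + n_g theta^2),
    log|V_g| = log(1 + n_g theta^2).

The profiled criteria are

    -2 l_REML(theta) = (n-p) (1 + log(2 pi s2)) + log|V| + log|X' V^-1 X|,
        s2 = r' V^-1 r / (n - p),
    -2 l_ML(theta)   = n (1 + log(2 pi s2)) + log|V|,
        s2 = r' V^-1 r / n,

with r the generalized-least-squares residual at theta. Variance components
and coefficients are taken at the REML optimum; likelihood-ratio chi-square
tests of fixed-effect terms refit both models under the ML criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dataio import FixedEffectSpec, MetabolomicsDataset, build_design

__all__ = ["LmmFit", "LrtResult", "reml_deviance", "fit_random_intercept",
           "lrt_term", "lrt_from_designs"]

#: optimizer bracket on theta = sigma_u / sigma_e and offset for the log scale
THETA_MAX = 100.0
THETA_EPS = 1e-8
#: convergence tolerance of the 1-D bounded search
XATOL = 1e-8
#: below this residual sum of squares a fit is treated as degenerate
DEGENERATE_RSS = 1e-12


@dataclass
class LmmFit:
    """One feature's fitted random-intercept model."""

    beta: np.ndarray
    beta_names: list[str]
    beta_se: np.ndarray            # Wald standard errors at the REML optimum
    sigma_u2: float
    sigma_e2: float
    theta: float
    blups: pd.Series               # per-subject predicted random effect
    fitted_marginal: np.ndarray    # X beta-hat
    fitted_conditional: np.ndarray  # X beta-hat + blup(subject)
    residuals: np.ndarray          # y - fitted_conditional
    loglik_reml: float
    loglik_ml: float
    converged: bool
    boundary: bool                 # sigma_u^2 estimated at 0
    degenerate: bool               # zero-variance response
    n_obs: int
    n_subjects: int

    @property
    def wald_chisq(self) -> np.ndarray:
        """Per-coefficient Wald chi-square (beta/se)^2."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.beta_se > 0,
                            (self.beta / self.beta_se) ** 2, np.nan)


@dataclass(frozen=True)
class LrtResult:
    chisq: float
    df: int
    p_value: float
    reliable: bool


def _group_codes(groups) -> tuple[np.ndarray, np.ndarray, list]:
    codes, uniques = pd.factorize(np.asarray(groups))
    counts = np.bincount(codes)
    return codes, counts, list(uniques)


def _profile(theta: float, y: np.ndarray, X: np.ndarray,
             codes: np.ndarray, counts: np.ndarray, reml: bool):
    """Deviance with beta and sigma_e^2 profiled out at fixed theta.

    Returns (deviance, beta, sigma_e2, A) where A = X' V^-1 X.
    """
    n, p = X.shape
    t2 = theta * theta
    w = t2 / (1.0 + counts * t2)          # per-group inverse weight
    G = len(counts)
    SX = np.zeros((G, p))
    np.add.at(SX, codes, X)
    Sy = np.bincount(codes, weights=y, minlength=G)
    A = X.T @ X - (SX * w[:, None]).T @ SX
    b = X.T @ y - SX.T @ (w * Sy)
    yVy = y @ y - w @ (Sy * Sy)
    beta = np.linalg.solve(A, b)
    rss = yVy - beta @ b                   # r' V^-1 r
    rss = max(rss, 0.0)
    logdetV = np.sum(np.log1p(counts * t2))
    dof = n - p if reml else n
    if rss < DEGENERATE_RSS:
        return -np.inf, beta, 0.0, A
    s2 = rss / dof
    dev = dof * (1.0 + np.log(2.0 * np.pi * s2)) + logdetV
    if reml:
        dev += np.linalg.slogdet(A)[1]
    return dev, beta, s2, A


def reml_deviance(theta: float, y, X, groups, *, reml: bool = True):
    """-2 log-(restricted-)likelihood at fixed theta = sigma_u/sigma_e.

    Beta and sigma_e^2 are profiled out in closed form via generalized least
    squares on V(theta) = I + theta^2 Z Z'. Only theta^2 enters, so the
    criterion is even in theta. Returns (deviance, beta, sigma_e2).

    Raises on a rank-deficient X. If every subject has a single observation,
    sigma_u^2 is unidentifiable; callers force theta = 0 in that case.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    codes, counts, _ = _group_codes(groups)
    dev, beta, s2, _ = _profile(theta, y, X, codes, counts, reml)
    return dev, beta, s2


def _optimize_theta(y, X, codes, counts, reml: bool):
    """Bounded 1-D minimization over log(theta + eps), boundary allowed."""
    def fun(phi):
        th = np.exp(phi) - THETA_EPS
        return _profile(max(th, 0.0), y, X, codes, counts, reml)[0]

    res = optimize.minimize_scalar(
        fun, bounds=(np.log(THETA_EPS), np.log(THETA_MAX + THETA_EPS)),
        method="bounded", options={"xatol": XATOL})
    theta = max(np.exp(res.x) - THETA_EPS, 0.0)
    dev = res.fun
    # the profiled deviance is flat near the boundary on the log scale;
    # accept theta = 0 whenever it is at least as good
    dev0 = _profile(0.0, y, X, codes, counts, reml)[0]
    if dev0 <= dev + 1e-10:
        theta, dev = 0.0, dev0
    return theta, dev, bool(res.success)


def fit_random_intercept(y, X, groups,
                         beta_names: list[str] | None = None,
                         subject_ids: list | None = None,
                         compute_ml: bool = True) -> LmmFit:
    """Fit the random-intercept model by profiled REML.

    Parameters
    ----------
    y, X, groups
        Response vector, full-rank design matrix (including intercept), and
        per-sample subject identifiers.
    beta_names, subject_ids
        Optional labels for coefficients and subjects.

    Singleton subjects are permitted; they inform the fixed effects while
    sigma_u^2 is identified from multi-observation subjects. If no subject has
    two observations, theta is forced to 0 and the fit flagged as boundary.
    A constant response yields a degenerate fit with both variances 0.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design matrix")
    codes, counts, uniq = _group_codes(groups)
    if subject_ids is None:
        subject_ids = uniq
    if beta_names is None:
        beta_names = [f"x{j}" for j in range(p)]
    G = len(counts)

    identifiable = bool((counts >= 2).any())
    degenerate = bool(np.ptp(y) < 1e-14)

    if degenerate:
        beta = np.zeros(p)
        # constant y: intercept column (if present) carries the constant
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        fitted = X @ beta
        return LmmFit(
            beta=beta, beta_names=list(beta_names),
            beta_se=np.zeros(p), sigma_u2=0.0, sigma_e2=0.0, theta=0.0,
            blups=pd.Series(np.zeros(G), index=subject_ids),
            fitted_marginal=fitted, fitted_conditional=fitted,
            residuals=y - fitted, loglik_reml=np.inf, loglik_ml=np.inf,
            converged=True, boundary=True, degenerate=True,
            n_obs=n, n_subjects=G)

    if identifiable:
        theta, dev_reml, ok = _optimize_theta(y, X, codes, counts, reml=True)
        if compute_ml:
            _, dev_ml, ok_ml = _optimize_theta(y, X, codes, counts, reml=False)
            ok = ok and ok_ml
        else:
            dev_ml = np.nan
    else:
        theta, ok = 0.0, True
        dev_reml = _profile(0.0, y, X, codes, counts, True)[0]
        dev_ml = (_profile(0.0, y, X, codes, counts, False)[0]
                  if compute_ml else np.nan)

    _, beta, sigma_e2, A = _profile(theta, y, X, codes, counts, reml=True)
    sigma_u2 = theta * theta * sigma_e2

    # Wald SEs from the GLS covariance sigma_e^2 (X' V^-1 X)^-1
    cov = sigma_e2 * np.linalg.inv(A)
    beta_se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    fitted_marginal = X @ beta
    marg_resid = y - fitted_marginal
    mean_resid = np.bincount(codes, weights=marg_resid, minlength=G) / counts
    denom = counts * sigma_u2 + sigma_e2
    with np.errstate(divide="ignore", invalid="ignore"):
        shrink = np.where(denom > 0, counts * sigma_u2 / denom, 0.0)
    blups = shrink * mean_resid
    fitted_conditional = fitted_marginal + blups[codes]

    return LmmFit(
        beta=beta, beta_names=list(beta_names), beta_se=beta_se,
        sigma_u2=sigma_u2, sigma_e2=sigma_e2, theta=theta,
        blups=pd.Series(blups, index=subject_ids),
        fitted_marginal=fitted_marginal,
        fitted_conditional=fitted_conditional,
        residuals=y - fitted_conditional,
        loglik_reml=-dev_reml / 2.0, loglik_ml=-dev_ml / 2.0,
        converged=ok, boundary=(theta == 0.0), degenerate=False,
        n_obs=n, n_subjects=G)


def _ml_loglik(y, X, codes, counts) -> tuple[float, bool]:
    _, dev, ok = _optimize_theta(y, X, codes, counts, reml=False)
    return -dev / 2.0, ok


def lrt_from_designs(y, X_full: np.ndarray, X_reduced: np.ndarray,
                     groups, df: int) -> LrtResult:
    """Likelihood-ratio chi-square test from explicit full/reduced designs.

    Both models are fitted under the ML criterion with the same
    random-intercept structure. Columns that are identically zero contribute
    nothing and are dropped before fitting.
    """
    y = np.asarray(y, dtype=float)
    codes, counts, _ = _group_codes(groups)

    def clean(X):
        X = np.asarray(X, dtype=float)
        keep = np.abs(X).sum(axis=0) > 0
        return X[:, keep]

    Xf, Xr = clean(X_full), clean(X_reduced)
    ll_full, ok_f = _ml_loglik(y, Xf, codes, counts)
    ll_red, ok_r = _ml_loglik(y, Xr, codes, counts)
    chisq = max(2.0 * (ll_full - ll_red), 0.0)
    p = float(stats.chi2.sf(chisq, df)) if df > 0 else 1.0
    if chisq == 0.0:
        p = 1.0
    return LrtResult(chisq=chisq, df=df, p_value=p, reliable=ok_f and ok_r)


def lrt_term(y, dataset: MetabolomicsDataset, spec: FixedEffectSpec,
             dropped_term: str, class_term: str = "class") -> LrtResult:
    """Chi-square test of one fixed-effect term by ML likelihood ratio.

    The term's design columns are removed to form the reduced model; the
    degrees of freedom equal the number of columns the term expands to.
    """
    if dropped_term not in spec.terms:
        raise ValueError(f"term {dropped_term!r} not in the fixed-effect spec")
    X_full = build_design(dataset, spec, class_term)
    reduced_terms = tuple(t for t in spec.terms if t != dropped_term)
    if reduced_terms:
        reduced = FixedEffectSpec(reduced_terms, spec.reference_levels)
        X_red = build_design(dataset, reduced, class_term)
    else:
        X_red = pd.DataFrame(
            {"(Intercept)": np.ones(dataset.n_samples)},
            index=dataset.abundances.index)
    df = X_full.shape[1] - X_red.shape[1]
    return lrt_from_designs(np.asarray(y, dtype=float),
                            X_full.to_numpy(), X_red.to_numpy(),
                            dataset.subject.to_numpy(), df)
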