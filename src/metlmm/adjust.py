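"""Whole-matrix processing: fit every feature, emit adjusted matrix + tables.

The processed value of a sample is, by default, the model's conditional
fitted value X beta-hat + u-hat (fixed effects plus the subject's predicted
random intercept) — the estimate of the noise-free abundance with residual
error removed. Two alternative readings are exposed as modes:

- "marginal":       X beta-hat only (subject effects removed entirely)
- "deduct_random":  y - u-hat (observed value minus the subject offset)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import FixedEffectSpec, MetabolomicsDataset, build_design
from .lmm_core import LmmFit, fit_random_intercept, lrt_from_designs

__all__ = ["ProcessedResult", "process_dataset", "recovery_report", "MODES"]

logger = logging.getLogger(__name__)

MODES = ("conditional", "marginal", "deduct_random")


@dataclass
class ProcessedResult:
    """Adjusted matrix plus per-feature model summaries."""

    processed: pd.DataFrame            # same shape/order as the input matrix
    mode: str
    coefficient_table: pd.DataFrame    # feature x term: estimate, chisq, df, p
    fit_summaries: pd.DataFrame        # per-feature sigma_u2, sigma_e2, flags
    skipped_features: dict[str, str] = field(default_factory=dict)
    fits: dict[str, LmmFit] = field(default_factory=dict)


def _term_columns(design: pd.DataFrame, spec: FixedEffectSpec,
                  class_term: str) -> dict[str, list[str]]:
    """Map each spec term to its design-matrix column names."""
    out: dict[str, list[str]] = {}
    for term in spec.terms:
        cols = [c for c in design.columns
                if c == term or c.startswith(f"{term}[")]
        out[term] = cols
    return out


def process_dataset(dataset: MetabolomicsDataset, spec: FixedEffectSpec,
                    mode: str = "conditional", *, class_term: str = "class",
                    compute_tests: bool = True,
                    drop_aliased: bool = False) -> ProcessedResult:
    """Fit the random-intercept model to every feature column.

    Features with zero variance or failed fits are passed through unchanged
    and listed in ``skipped_features``. Per-feature models are independent, so
    the result does not depend on evaluation order.

    Parameters
    ----------
    mode
        "conditional" (default), "marginal" or "deduct_random"; see module
        docstring.
    compute_tests
        When True, a likelihood-ratio chi-square test (ML criterion) is run
        for every term of every feature; switch off to fit only (used by the
        cross-validation harness where only processed values are needed).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    design = build_design(dataset, spec, class_term, drop_aliased=drop_aliased)
    X = design.to_numpy()
    col_names = list(design.columns)
    groups = dataset.subject.to_numpy()
    term_cols = _term_columns(design, spec, class_term)

    processed = dataset.abundances.copy()
    coef_rows = []
    fit_rows = []
    skipped: dict[str, str] = {}
    fits: dict[str, LmmFit] = {}

    for fid in dataset.feature_ids:
        y = dataset.abundances[fid].to_numpy(dtype=float)
        if np.ptp(y) < 1e-14:
            skipped[fid] = "zero variance"
            logger.info("feature %s skipped: zero variance", fid)
            continue
        fit = fit_random_intercept(y, X, groups, beta_names=col_names,
                                   compute_ml=compute_tests)
        if not fit.converged:
            skipped[fid] = "non-convergent fit"
            logger.warning("feature %s skipped: optimizer did not converge", fid)
            continue
        fits[fid] = fit
        if mode == "conditional":
            processed[fid] = fit.fitted_conditional
        elif mode == "marginal":
            processed[fid] = fit.fitted_marginal
        else:  # deduct_random
            blup_per_sample = fit.fitted_conditional - fit.fitted_marginal
            processed[fid] = y - blup_per_sample
        fit_rows.append({
            "feature": fid, "sigma_u2": fit.sigma_u2, "sigma_e2": fit.sigma_e2,
            "theta": fit.theta, "loglik_reml": fit.loglik_reml,
            "converged": fit.converged, "boundary": fit.boundary})
        beta = dict(zip(fit.beta_names, fit.beta))
        se = dict(zip(fit.beta_names, fit.beta_se))
        wald = dict(zip(fit.beta_names, fit.wald_chisq))
        for term, cols in term_cols.items():
            if compute_tests:
                keep = [c for c in col_names if c not in cols]
                Xr = design[keep].to_numpy()
                lrt = lrt_from_designs(y, X, Xr, groups, df=len(cols))
                chisq, df, p, rel = lrt.chisq, lrt.df, lrt.p_value, lrt.reliable
            else:
                chisq = df = p = np.nan
                rel = True
            for col in cols:
                coef_rows.append({
                    "feature": fid, "term": term, "column": col,
                    "estimate": beta[col], "se": se[col],
                    "wald_chisq": wald[col],
                    "chisq": chisq, "df": df, "p_value": p,
                    "reliable": rel})

    coef_table = pd.DataFrame(
        coef_rows, columns=["feature", "term", "column", "estimate", "se",
                            "wald_chisq", "chisq", "df", "p_value", "reliable"])
    fit_summaries = pd.DataFrame(
        fit_rows, columns=["feature", "sigma_u2", "sigma_e2", "theta",
                           "loglik_reml", "converged", "boundary"])
    return ProcessedResult(
        processed=processed, mode=mode, coefficient_table=coef_table,
        fit_summaries=fit_summaries, skipped_features=skipped, fits=fits)


def recovery_report(result: ProcessedResult,
                    truth: pd.DataFrame) -> pd.DataFrame:
    """Bias/RMSE of coefficient estimates against known generator truth.

    ``truth`` is a feature x design-column frame of true coefficient values
    (as produced by the synthetic cohort generator). Returns a per-column
    table with bias = mean(estimate - true) and RMSE over features.
    """
    est = result.coefficient_table.pivot(
        index="feature", columns="column", values="estimate")
    common_cols = [c for c in truth.columns if c in est.columns]
    if not set(est.index) <= set(truth.index):
        extra = sorted(set(est.index) - set(truth.index))
        raise ValueError(f"features missing from truth: {extra}")
    rows = []
    for col in common_cols:
        diff = est[col] - truth.loc[est.index, col]
        rows.append({"column": col,
                     "bias": float(diff.mean()),
                     "rmse": float(np.sqrt((diff ** 2).mean())),
                     "n_features": int(diff.notna().sum())})
    return pd.DataFrame(rows, columns=["column", "bias", "rmse", "n_features"])
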