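"""Read-only diagnostics: within-group RLA, variance change, PCA scores.

The within-group relative log abundance (RLA) plot shows, per sample, the
distribution of deviations of each feature from that feature's median within
the sample's class group — a standard visual check of between-subject
variability. These functions never modify data passed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RlaSummary", "rla_within", "variance_change", "pca_scores"]


@dataclass
class RlaSummary:
    deviations: pd.DataFrame       # n_samples x n_features
    per_sample_stats: pd.DataFrame  # median, q1, q3, iqr per sample
    groups: pd.Series


def rla_within(X, groups) -> RlaSummary:
    """Deviation of each feature from its within-group median.

    Per class group, the feature's median over the group's samples is
    subtracted from every sample of that group; per-sample quartile summaries
    of the deviations are returned for boxplot construction.
    """
    was_df = isinstance(X, pd.DataFrame)
    Xdf = X if was_df else pd.DataFrame(np.asarray(X, dtype=float))
    groups = pd.Series(np.asarray(groups), index=Xdf.index)
    medians = Xdf.groupby(groups).transform("median")
    dev = Xdf - medians
    stats = pd.DataFrame({
        "median": dev.median(axis=1),
        "q1": dev.quantile(0.25, axis=1),
        "q3": dev.quantile(0.75, axis=1),
    })
    stats["iqr"] = stats["q3"] - stats["q1"]
    return RlaSummary(deviations=dev, per_sample_stats=stats, groups=groups)


def variance_change(before, after) -> pd.DataFrame:
    """Per-feature sample variance before/after processing and the ratio.

    A ratio below 1 means the processing step reduced that feature's spread
    across samples. Constant columns give a ratio of 0 (after constant) or
    NaN (before constant).
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape:
        raise ValueError(f"shape mismatch: {b.shape} vs {a.shape}")
    names = (list(before.columns) if isinstance(before, pd.DataFrame)
             else [f"f{j}" for j in range(b.shape[1])])
    vb = b.var(axis=0, ddof=1)
    va = a.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(vb > 0, va / vb, np.nan)
    return pd.DataFrame({"var_before": vb, "var_after": va, "ratio": ratio},
                        index=names)


def pca_scores(X, n_components: int, scale: bool = False):
    """Centered (optionally autoscaled) PCA via SVD.

    Returns (scores, explained_fractions). Scores use the sign convention of
    the latent-variable models (first nonzero loading entry positive).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise ValueError(f"n_components={n_components} exceeds min(n-1, p)="
                         f"{min(n - 1, p)}")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        Xc = Xc / np.where(sd > 0, sd, 1.0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = (S ** 2).sum()
    frac = (S[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    scores = U[:, :n_components] * S[:n_components]
    for a in range(n_components):
        v = Vt[a]
        nz = np.flatnonzero(np.abs(v) > 1e-12)
        if nz.size and v[nz[0]] < 0:
            scores[:, a] = -scores[:, a]
    return scores, frac
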