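"""PLS-DA, OPLS-DA, VIP scoring and the multilevel within-subject split.

Binary discriminant analysis on a samples x features matrix. The class label
is encoded as a centered 0/1 dummy response; predictive components are
extracted with the NIPALS weight/score alternation and X-deflation, and
OPLS-DA first strips components orthogonal to the response (orthogonal
projections to latent structures). Feature relevance is summarized by the
variable importance in projection (VIP); features with VIP > 1 are called
discriminative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LatentModel", "plsda_fit", "oplsda_fit", "vip",
           "within_variation", "predict_class", "select_discriminative"]


@dataclass
class LatentModel:
    """Fitted (O)PLS-DA model with preprocessing state for projection."""

    kind: str                       # "PLSDA" | "OPLSDA"
    n_components: int               # predictive components
    n_ortho: int                    # orthogonal components (OPLSDA only)
    weights: np.ndarray             # p x A, unit-norm NIPALS weights
    loadings: np.ndarray            # p x A
    scores: np.ndarray              # n x A
    y_loadings: np.ndarray          # A,
    ortho_weights: np.ndarray       # p x n_ortho
    ortho_loadings: np.ndarray      # p x n_ortho
    ortho_scores: np.ndarray        # n x n_ortho
    center_vector: np.ndarray
    scale_vector: np.ndarray
    class_levels: tuple[str, str]
    feature_ids: list[str]
    vip: np.ndarray
    ss_components: np.ndarray       # response variance explained per component
    decision_threshold: float
    positive_high: bool             # second class level has higher mean score
    y_mean: float = 0.0
    train_scores_decision: np.ndarray = field(default=None, repr=False)


def _sign_fix(w: np.ndarray) -> float:
    """Sign making the first nonzero weight entry positive (reproducibility)."""
    nz = np.flatnonzero(np.abs(w) > 1e-12)
    if nz.size == 0:
        return 1.0
    return 1.0 if w[nz[0]] > 0 else -1.0


def _preprocess(X: np.ndarray, scale: bool):
    center = X.mean(axis=0)
    Xc = X - center
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)   # zero-variance columns untouched
    else:
        sd = np.ones(X.shape[1])
    return Xc / sd, center, sd


def _dummy(labels, class_levels: tuple[str, str]) -> np.ndarray:
    labels = np.asarray(labels).astype(str)
    present = set(labels)
    if len(present) < 2:
        raise ValueError("need two classes present, got " + repr(sorted(present)))
    extra = present - set(class_levels)
    if extra:
        raise ValueError(f"labels outside class levels: {sorted(extra)}")
    return (labels == class_levels[1]).astype(float)


def _nipals(Xc: np.ndarray, yc: np.ndarray, n_components: int):
    """PLS1 component extraction with X- and y-deflation.

    Returns unit-norm weights W, loadings P, scores T, y-loadings q and the
    per-component explained response variance SS_a = q_a^2 t_a' t_a.
    """
    n, p = Xc.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    ss = np.zeros(n_components)
    X = Xc.copy()
    y = yc.copy()
    for a in range(n_components):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            raise ValueError(
                f"component {a + 1}: no covariance left between X and the response")
        w /= nw
        w *= _sign_fix(w)
        t = X @ w
        tt = t @ t
        if tt < 1e-12:
            raise ValueError(f"component {a + 1}: degenerate score vector")
        pl = X.T @ t / tt
        qa = y @ t / tt
        X = X - np.outer(t, pl)
        y = y - qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, pl, t, qa
        ss[a] = qa * qa * tt
    return W, P, T, q, ss


def _vip_scores(W: np.ndarray, ss: np.ndarray) -> np.ndarray:
    """VIP_j = sqrt(p * sum_a SS_a w_aj^2 / sum_a SS_a) for unit-norm w_a."""
    total = ss.sum()
    if total <= 0:
        raise ValueError("zero explained response variance; degenerate model")
    p = W.shape[0]
    return np.sqrt(p * (W ** 2 @ ss) / total)


def _decision_setup(scores_decision: np.ndarray, dummy: np.ndarray):
    mean1 = scores_decision[dummy == 1].mean()
    mean0 = scores_decision[dummy == 0].mean()
    return (mean0 + mean1) / 2.0, mean1 > mean0


def plsda_fit(X, labels, n_components: int = 2, scale: bool = True,
              class_levels: tuple[str, str] | None = None,
              feature_ids: list[str] | None = None) -> LatentModel:
    """Fit a binary PLS-DA model by NIPALS.

    Columns are mean-centered (and unit-variance scaled when ``scale``); the
    response is the centered indicator of the second class level. Output is
    deterministic: each weight vector is signed so its first nonzero entry is
    positive.
    """
    if isinstance(X, pd.DataFrame):
        feature_ids = feature_ids or list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(X.shape[1])]
    if class_levels is None:
        class_levels = tuple(sorted(set(np.asarray(labels).astype(str))))[:2]
    dummy = _dummy(labels, class_levels)
    Xs, center, sd = _preprocess(X, scale)
    rank = np.linalg.matrix_rank(Xs)
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank} "
                         "of the centered matrix")
    yc = dummy - dummy.mean()
    W, P, T, q, ss = _nipals(Xs, yc, n_components)
    vip_scores = _vip_scores(W, ss)
    decision = T @ q
    thr, pos_high = _decision_setup(decision, dummy)
    return LatentModel(
        kind="PLSDA", n_components=n_components, n_ortho=0,
        weights=W, loadings=P, scores=T, y_loadings=q,
        ortho_weights=np.zeros((X.shape[1], 0)),
        ortho_loadings=np.zeros((X.shape[1], 0)),
        ortho_scores=np.zeros((X.shape[0], 0)),
        center_vector=center, scale_vector=sd,
        class_levels=tuple(class_levels), feature_ids=list(feature_ids),
        vip=vip_scores, ss_components=ss,
        decision_threshold=thr, positive_high=pos_high,
        y_mean=dummy.mean(), train_scores_decision=decision)


def oplsda_fit(X, labels, n_ortho: int = 1, scale: bool = True,
               class_levels: tuple[str, str] | None = None,
               feature_ids: list[str] | None = None) -> LatentModel:
    """Fit a binary OPLS-DA model: n_ortho orthogonal-filter components
    followed by one predictive component.

    Each orthogonal component is built from the X-loading of the provisional
    predictive direction with its response-aligned part removed
    (w_o = p - (w'p) w), so orthogonal scores are exactly uncorrelated with
    the dummy response. The filtered matrix X - t_o p_o' then yields the
    predictive component. VIP uses the predictive component only.
    """
    if isinstance(X, pd.DataFrame):
        feature_ids = feature_ids or list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(X.shape[1])]
    if class_levels is None:
        class_levels = tuple(sorted(set(np.asarray(labels).astype(str))))[:2]
    dummy = _dummy(labels, class_levels)
    Xs, center, sd = _preprocess(X, scale)
    rank = np.linalg.matrix_rank(Xs)
    if n_ortho > rank:
        raise ValueError(f"n_ortho={n_ortho} exceeds rank {rank} of the "
                         "centered matrix")
    # a rank-1 matrix aligned with the response is legal: the orthogonal
    # component then degenerates to zero and only the predictive part remains
    yc = dummy - dummy.mean()

    p_feat, n = X.shape[1], X.shape[0]
    Wo = np.zeros((p_feat, n_ortho))
    Po = np.zeros((p_feat, n_ortho))
    To = np.zeros((n, n_ortho))
    Xf = Xs.copy()
    for a in range(n_ortho):
        w = Xf.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            raise ValueError("no covariance left between X and the response")
        w /= nw
        t = Xf @ w
        pl = Xf.T @ t / (t @ t)
        w_o = pl - (w @ pl) * w
        nwo = np.linalg.norm(w_o)
        if nwo < 1e-12:
            # nothing orthogonal to remove; keep a zero component
            Wo[:, a] = 0.0
            continue
        w_o /= nwo
        w_o *= _sign_fix(w_o)
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / (t_o @ t_o)
        Xf = Xf - np.outer(t_o, p_o)
        Wo[:, a], Po[:, a], To[:, a] = w_o, p_o, t_o

    W, P, T, q, ss = _nipals(Xf, yc, 1)
    vip_scores = _vip_scores(W, ss)
    decision = T @ q
    thr, pos_high = _decision_setup(decision, dummy)
    return LatentModel(
        kind="OPLSDA", n_components=1, n_ortho=n_ortho,
        weights=W, loadings=P, scores=T, y_loadings=q,
        ortho_weights=Wo, ortho_loadings=Po, ortho_scores=To,
        center_vector=center, scale_vector=sd,
        class_levels=tuple(class_levels), feature_ids=list(feature_ids),
        vip=vip_scores, ss_components=ss,
        decision_threshold=thr, positive_high=pos_high,
        y_mean=dummy.mean(), train_scores_decision=decision)


def vip(model: LatentModel) -> np.ndarray:
    """Per-feature variable importance in projection (predictive components
    only). mean(VIP^2) = 1 by construction."""
    return model.vip


def within_variation(X, subjects) -> pd.DataFrame | np.ndarray:
    """Multilevel within-subject matrix: X - subject means + grand mean.

    Removes the between-subject level so that multivariate analysis sees only
    within-subject (e.g. between-tissue) variation. Idempotent; singleton
    subjects map to the grand-mean row.
    """
    was_df = isinstance(X, pd.DataFrame)
    Xdf = X if was_df else pd.DataFrame(np.asarray(X, dtype=float))
    subjects = pd.Series(np.asarray(subjects), index=Xdf.index)
    subj_means = Xdf.groupby(subjects).transform("mean")
    out = Xdf - subj_means + Xdf.mean(axis=0)
    return out if was_df else out.to_numpy()


def _project_decision(model: LatentModel, X_new: np.ndarray) -> np.ndarray:
    Xc = (X_new - model.center_vector) / model.scale_vector
    for a in range(model.n_ortho):
        w_o = model.ortho_weights[:, a]
        if np.linalg.norm(w_o) < 1e-12:
            continue
        t_o = Xc @ w_o
        Xc = Xc - np.outer(t_o, model.ortho_loadings[:, a])
    # rotation absorbing NIPALS deflation: T_new = Xc W (P'W)^-1
    R = model.weights @ np.linalg.inv(model.loadings.T @ model.weights)
    T_new = Xc @ R
    return T_new @ model.y_loadings


def predict_class(model: LatentModel, X_new):
    """Predict labels for new samples.

    X_new must carry the model's feature set (a DataFrame is aligned by
    feature id; missing features are an error naming them). Returns
    (labels, decision_scores); the threshold is the midpoint of the training
    decision-score class means, ties resolve to the first class level.
    """
    if isinstance(X_new, pd.DataFrame):
        missing = [f for f in model.feature_ids if f not in X_new.columns]
        if missing:
            raise ValueError(f"missing features in new data: {missing}")
        X_new = X_new[model.feature_ids].to_numpy(dtype=float)
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != len(model.feature_ids):
        raise ValueError(
            f"expected {len(model.feature_ids)} features, got {X_new.shape[1]}")
    scores = _project_decision(model, X_new)
    first, second = model.class_levels
    if model.positive_high:
        labels = np.where(scores > model.decision_threshold, second, first)
    else:
        labels = np.where(scores < model.decision_threshold, second, first)
    # exact tie -> first class level (enforced: strict comparisons above
    # already send the tie to `first`)
    return labels, scores


def select_discriminative(model: LatentModel,
                          threshold: float = 1.0) -> pd.Series:
    """Features with VIP strictly above threshold, sorted by descending VIP."""
    s = pd.Series(model.vip, index=model.feature_ids)
    s = s[s > threshold]
    return s.sort_values(ascending=False, kind="mergesort")
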