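"""Cross-validated comparison of processing arms (the prediction harness).

The harness partitions a paired cohort into repeated k-fold train/test
splits, processes each training fold with one of three arms —

- M0:  original log2 data, no extra processing
- LMM: per-feature random-intercept mixed-model adjustment
- ML:  multilevel within-subject decomposition

— fits PLS-DA (and OPLS-DA for M0/LMM) on the processed fold, selects
discriminative features at VIP > 1, trains a fresh PLS classifier on the
selected features, and scores the untouched original-scale test fold with
accuracy, precision, sensitivity and specificity. Arms are compared across
splits with Wilcoxon signed-rank tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .adjust import process_dataset
from .dataio import FixedEffectSpec, MetabolomicsDataset
from .multivariate import (oplsda_fit, plsda_fit, predict_class,
                           select_discriminative, within_variation)

__all__ = ["SplitPlan", "EvaluationReport", "make_splits", "run_evaluation",
           "confusion_metrics", "wilcoxon_signed_rank"]

logger = logging.getLogger(__name__)

METRICS = ("accuracy", "precision", "sensitivity", "specificity")


@dataclass(frozen=True)
class SplitPlan:
    splits: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    k: int
    repeats: int
    seed: int
    grouping: str  # "subject" | "sample"


@dataclass
class EvaluationReport:
    per_split: pd.DataFrame   # split, repeat, fold, arm, metrics, n_selected
    summary: pd.DataFrame     # arm x metric -> mean, sd
    comparisons: pd.DataFrame  # arm pair x metric -> statistic, p, n_effective
    skipped: list[str] = field(default_factory=list)


def make_splits(dataset: MetabolomicsDataset, k: int = 4, repeats: int = 5,
                seed: int = 0, grouping: str = "subject") -> SplitPlan:
    """Repeated k-fold split plan, reproducible from the seed.

    Subject-level grouping (default) rotates whole subjects through folds so
    no subject spans train and test; in a paired design this preserves class
    balance automatically. Sample-level grouping stratifies by class.
    """
    if grouping not in ("subject", "sample"):
        raise ValueError(f"unknown grouping {grouping!r}")
    rng = np.random.default_rng(seed)
    splits: list[tuple[tuple[str, ...], tuple[str, ...]]] = []
    all_ids = np.array(dataset.sample_ids)

    if grouping == "subject":
        subjects = np.array(sorted(dataset.subject.unique().astype(str)))
        if k > len(subjects):
            raise ValueError(f"k={k} exceeds {len(subjects)} subjects")
        subj_of = dataset.subject.astype(str)
        for _ in range(repeats):
            order = rng.permutation(len(subjects))
            folds = [subjects[order[f::k]] for f in range(k)]
            for fold in folds:
                test_mask = subj_of.isin(fold).to_numpy()
                splits.append((tuple(all_ids[~test_mask]),
                               tuple(all_ids[test_mask])))
    else:
        labels = dataset.class_label.astype(str).to_numpy()
        if k > len(all_ids):
            raise ValueError(f"k={k} exceeds {len(all_ids)} samples")
        for _ in range(repeats):
            fold_of = np.empty(len(all_ids), dtype=int)
            for lev in sorted(set(labels)):
                idx = np.flatnonzero(labels == lev)
                idx = idx[rng.permutation(len(idx))]
                fold_of[idx] = np.arange(len(idx)) % k
            for f in range(k):
                mask = fold_of == f
                splits.append((tuple(all_ids[~mask]), tuple(all_ids[mask])))

    return SplitPlan(splits=tuple(splits), k=k, repeats=repeats, seed=seed,
                     grouping=grouping)


def confusion_metrics(truth, predicted, positive: str) -> dict[str, float]:
    """Accuracy, precision, sensitivity, specificity for one binary split.

    Ratios with a zero denominator come back as NaN (excluded from summaries
    with a log entry).
    """
    truth = np.asarray(truth).astype(str)
    predicted = np.asarray(predicted).astype(str)
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted differ in length")
    if positive not in set(truth) | set(predicted):
        raise ValueError(f"unknown positive label {positive!r}")
    tp = int(((truth == positive) & (predicted == positive)).sum())
    tn = int(((truth != positive) & (predicted != positive)).sum())
    fp = int(((truth != positive) & (predicted == positive)).sum())
    fn = int(((truth == positive) & (predicted != positive)).sum())

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    return {
        "accuracy": ratio(tp + tn, tp + tn + fp + fn),
        "precision": ratio(tp, tp + fp),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
    }


# -- Wilcoxon signed-rank --------------------------------------------------

def _exact_cdf_le(w: float, ranks: np.ndarray) -> float:
    """P(W+ <= w) under the null by dynamic-programming enumeration.

    Valid for integer ranks (no ties). Equivalent to summing over all 2^n
    sign patterns.
    """
    total = int(ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks.astype(int):
        counts[r:] += counts[:-r] if r > 0 else counts
    counts /= counts.sum()
    return float(counts[: int(np.floor(w)) + 1].sum())


def wilcoxon_signed_rank(a, b):
    """Paired two-sided Wilcoxon signed-rank test.

    Zero differences are dropped; absolute differences are midranked. The
    p-value is exact (full enumeration of sign patterns via dynamic
    programming) when the effective n is at most 25 and there are no ties in
    the absolute differences, otherwise a normal approximation with
    continuity and tie corrections is used. Returns
    (statistic = min(W+, W-), p_value, n_effective).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 1:
        raise ValueError("need two equal-length 1-D vectors of length >= 1")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0, 0
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    stat = min(w_plus, w_minus)
    ties = len(np.unique(np.abs(d))) < n
    if n <= 25 and not ties:
        p = min(1.0, 2.0 * _exact_cdf_le(stat, ranks))
        return stat, p, n
    mu = n * (n + 1) / 4.0
    _, t_counts = np.unique(ranks, return_counts=True)
    tie_corr = float(((t_counts ** 3 - t_counts) / 48.0).sum())
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr
    if sigma2 <= 0:
        return stat, 1.0, n
    diff = w_plus - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(sigma2)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return stat, p, n


# -- the harness -----------------------------------------------------------

ARM_MODELS = {
    "m0": ("plsda", "oplsda"),
    "lmm": ("plsda", "oplsda"),
    "ml": ("plsda",),          # multilevel arm pairs with PLS-DA only
}


def _arm_name(arm: str, model: str) -> str:
    return f"{arm.upper()}-{model.upper()}"


def _process_arm(arm: str, train_ds: MetabolomicsDataset,
                 spec: FixedEffectSpec | None, mode: str,
                 class_term: str) -> pd.DataFrame:
    if arm == "m0":
        return train_ds.abundances
    if arm == "lmm":
        if spec is None:
            raise ValueError("LMM arm requires a fixed-effect spec")
        res = process_dataset(train_ds, spec, mode, class_term=class_term,
                              compute_tests=False, drop_aliased=True)
        return res.processed
    if arm == "ml":
        counts = train_ds.subject.value_counts()
        if (counts < 2).all():
            raise ValueError("multilevel arm needs at least one subject with "
                             ">= 2 samples in the training fold")
        return within_variation(train_ds.abundances,
                                train_ds.subject.to_numpy())
    raise ValueError(f"unknown arm {arm!r}")


def _fit_selector(model_kind: str, Xtr: pd.DataFrame, labels, levels,
                  n_components: int, n_ortho: int, scale: bool):
    if model_kind == "plsda":
        rank = np.linalg.matrix_rank(Xtr.to_numpy() - Xtr.to_numpy().mean(0))
        return plsda_fit(Xtr, labels, n_components=min(n_components, rank),
                         scale=scale, class_levels=levels)
    return oplsda_fit(Xtr, labels, n_ortho=n_ortho, scale=scale,
                      class_levels=levels)


def run_evaluation(dataset: MetabolomicsDataset, spec: FixedEffectSpec | None,
                   plan: SplitPlan, arms=("m0", "lmm", "ml"),
                   *, n_components: int = 2, n_ortho: int = 1,
                   classifier_components: int = 1,
                   scale: bool = False, mode: str = "conditional",
                   positive: str | None = None,
                   class_term: str = "class") -> EvaluationReport:
    """Run the full arm comparison over a split plan.

    Per split and arm: process the training fold, fit the latent model,
    select features at VIP > 1 (falling back to all features when the
    selection is empty, logged), train a fresh PLS-DA classifier on the
    selected features of the processed fold, and predict the untouched
    original-scale test rows restricted to those features.

    The harness defaults differ from the standalone latent-model defaults:
    columns are centered but not unit-variance scaled (per-feature scale
    factors estimated on a processed training fold do not transfer to the
    raw test fold), and the final classifier uses one predictive component
    (a binary dummy response spans a single dimension; further components
    model X-variance and overfit). The selector model keeps ``n_components``.
    """
    levels = dataset.class_levels
    if positive is None:
        positive = levels[1]
    rows = []
    skipped: list[str] = []

    for s_idx, (train_ids, test_ids) in enumerate(plan.splits):
        train_ds = dataset.subset_samples(list(train_ids))
        test_ab = dataset.abundances.loc[list(test_ids)]
        test_truth = dataset.class_label.loc[list(test_ids)].astype(str)
        train_labels = train_ds.class_label.astype(str).to_numpy()
        if len(set(train_labels)) < 2:
            skipped.append(f"split {s_idx}: training fold missing a class")
            logger.warning("split %d skipped: training fold missing a class",
                           s_idx)
            continue
        for arm in arms:
            try:
                Xtr = _process_arm(arm, train_ds, spec, mode, class_term)
            except ValueError as exc:
                if arm == "ml":
                    raise
                skipped.append(f"split {s_idx} arm {arm}: {exc}")
                logger.warning("split %d arm %s skipped: %s", s_idx, arm, exc)
                continue
            for model_kind in ARM_MODELS[arm]:
                sel_model = _fit_selector(model_kind, Xtr, train_labels,
                                          levels, n_components, n_ortho, scale)
                selected = select_discriminative(sel_model, 1.0)
                feats = list(selected.index)
                if not feats:
                    feats = list(Xtr.columns)
                    logger.info("split %d %s: empty VIP selection, falling "
                                "back to all features", s_idx,
                                _arm_name(arm, model_kind))
                Xsel = Xtr[feats]
                rank = np.linalg.matrix_rank(
                    Xsel.to_numpy() - Xsel.to_numpy().mean(0))
                clf = plsda_fit(
                    Xsel, train_labels,
                    n_components=max(1, min(classifier_components, rank)),
                    scale=scale, class_levels=levels)
                pred, _ = predict_class(clf, test_ab[feats])
                m = confusion_metrics(test_truth.to_numpy(), pred, positive)
                rows.append({"split": s_idx,
                             "repeat": s_idx // plan.k,
                             "fold": s_idx % plan.k,
                             "arm": _arm_name(arm, model_kind),
                             "n_selected": len(selected), **m})

    per_split = pd.DataFrame(rows)
    if per_split.empty:
        raise ValueError("no split produced a result")

    nan_cells = int(per_split[list(METRICS)].isna().sum().sum())
    if nan_cells:
        logger.info("%d undefined metric value(s) excluded from summaries",
                    nan_cells)
    summary = (per_split.groupby("arm")[list(METRICS)]
               .agg(["mean", "std"]))

    comp_rows = []
    pairs = [("LMM-PLSDA", "M0-PLSDA"), ("LMM-PLSDA", "ML-PLSDA"),
             ("LMM-OPLSDA", "M0-OPLSDA")]
    by_arm = {arm: g.set_index("split") for arm, g in per_split.groupby("arm")}
    for arm_a, arm_b in pairs:
        if arm_a not in by_arm or arm_b not in by_arm:
            continue
        common = by_arm[arm_a].index.intersection(by_arm[arm_b].index)
        for metric in METRICS:
            va = by_arm[arm_a].loc[common, metric]
            vb = by_arm[arm_b].loc[common, metric]
            ok = va.notna() & vb.notna()
            if ok.sum() == 0:
                continue
            stat, p, n_eff = wilcoxon_signed_rank(va[ok].to_numpy(),
                                                  vb[ok].to_numpy())
            comp_rows.append({"comparison": f"{arm_a} vs {arm_b}",
                              "metric": metric, "statistic": stat,
                              "p_value": p, "n_effective": n_eff})
    comparisons = pd.DataFrame(
        comp_rows, columns=["comparison", "metric", "statistic", "p_value",
                            "n_effective"])
    return EvaluationReport(per_split=per_split, summary=summary,
                            comparisons=comparisons, skipped=skipped)
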