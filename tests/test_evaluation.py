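import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from metlmm import (CohortConfig, CovariateInfo, FixedEffectSpec,
                    MetabolomicsDataset, confusion_metrics, generate_cohort,
                    make_splits, run_evaluation, wilcoxon_signed_rank)
from metlmm.evaluation import SplitPlan


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(CohortConfig(n_subjects=20, n_features=15, seed=31))


def test_splits_partition_each_repeat(cohort):
    ds, _ = cohort
    plan = make_splits(ds, k=4, repeats=3, seed=1)
    assert len(plan.splits) == 12
    for r in range(3):
        test_union = []
        for f in range(4):
            train, test = plan.splits[r * 4 + f]
            assert set(train).isdisjoint(test)
            assert set(train) | set(test) == set(ds.sample_ids)
            test_union.extend(test)
        assert sorted(test_union) == sorted(ds.sample_ids)


def test_subject_level_split_never_spans_subjects(cohort):
    ds, _ = cohort
    plan = make_splits(ds, k=4, repeats=2, seed=2)
    subj = ds.subject
    for train, test in plan.splits:
        assert set(subj.loc[list(train)]).isdisjoint(subj.loc[list(test)])


def test_study_sized_plan_fold_sizes():
    """59 paired subjects, k=4 x 5 repeats: folds of 14-15 subjects."""
    ds, _ = generate_cohort(CohortConfig(n_subjects=59, n_features=2, seed=5))
    plan = make_splits(ds, k=4, repeats=5, seed=3)
    assert len(plan.splits) == 20
    sizes = {len(test) for _, test in plan.splits}
    assert sizes <= {28, 30}  # 14 or 15 subjects x 2 samples


def test_split_determinism(cohort):
    ds, _ = cohort
    assert make_splits(ds, seed=7) == make_splits(ds, seed=7)
    assert make_splits(ds, seed=7) != make_splits(ds, seed=8)


def test_sample_level_stratification(cohort):
    ds, _ = cohort
    plan = make_splits(ds, k=4, repeats=1, seed=4, grouping="sample")
    for _, test in plan.splits:
        labs = ds.class_label.loc[list(test)]
        assert abs((labs == "A").sum() - (labs == "B").sum()) <= 2


def test_confusion_metric_arithmetic():
    truth = ["P"] * 5 + ["N"] * 5
    pred = ["P", "P", "P", "N", "N", "P", "N", "N", "N", "N"]
    m = confusion_metrics(truth, pred, positive="P")
    assert m["accuracy"] == pytest.approx(0.7)
    assert m["precision"] == pytest.approx(0.75)
    assert m["sensitivity"] == pytest.approx(0.6)
    assert m["specificity"] == pytest.approx(0.8)
    perfect = confusion_metrics(truth, truth, positive="P")
    assert all(v == 1.0 for v in perfect.values())


def test_confusion_undefined_precision_is_nan():
    m = confusion_metrics(["P", "P", "N"], ["N", "N", "N"], positive="P")
    assert np.isnan(m["precision"])
    assert m["sensitivity"] == 0.0
    with pytest.raises(ValueError, match="positive"):
        confusion_metrics(["P"], ["P"], positive="X")


def test_wilcoxon_identical_vectors():
    stat, p, n = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert (stat, p, n) == (0.0, 1.0, 0)


def test_wilcoxon_exact_five_positive_differences():
    _, p, n = wilcoxon_signed_rank([1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
    assert p == pytest.approx(2 / 32)
    assert n == 5


def test_wilcoxon_matches_scipy_exact():
    rng = np.random.default_rng(5)
    for _ in range(10):
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        stat, p, _ = wilcoxon_signed_rank(a, b)
        ref = sps.wilcoxon(a, b, mode="exact")
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


def test_wilcoxon_normal_approximation_close_to_exact():
    rng = np.random.default_rng(6)
    a = rng.normal(0.3, 1, 20)
    b = rng.normal(0.0, 1, 20)
    _, p_exact, n = wilcoxon_signed_rank(a, b)
    assert n == 20
    ref = sps.wilcoxon(a, b, correction=True, mode="approx")
    assert abs(p_exact - ref.pvalue) < 0.02


def _separable_dataset():
    rng = np.random.default_rng(7)
    n_subj = 8
    rows = []
    for i in range(n_subj):
        for c in ("A", "B"):
            rows.append((f"p{i}_{c}", f"p{i}", c))
    idx = pd.Index([r[0] for r in rows], name="sample_id")
    labels = pd.Series([r[2] for r in rows], index=idx)
    signal = (labels == "B").astype(float) * 6.0
    X = pd.DataFrame({
        "m1": signal + rng.normal(0, 0.1, len(idx)),
        "m2": -signal + rng.normal(0, 0.1, len(idx)),
        "m3": rng.normal(0, 0.1, len(idx)),
    }, index=idx)
    return MetabolomicsDataset(
        abundances=X,
        subject=pd.Series([r[1] for r in rows], index=idx),
        class_label=labels, class_levels=("A", "B"))


def test_perfectly_separable_split_scores_ones():
    ds = _separable_dataset()
    plan = make_splits(ds, k=2, repeats=1, seed=1)
    rep = run_evaluation(ds, None, plan, arms=("m0", "ml"))
    assert np.allclose(rep.per_split[["accuracy", "precision", "sensitivity",
                                      "specificity"]], 1.0)


def test_no_leak_from_test_fold():
    """Removing a test sample from a split leaves training-side results
    (feature selection size, other predictions) unchanged."""
    ds, _ = generate_cohort(CohortConfig(n_subjects=12, n_features=10, seed=9))
    plan = make_splits(ds, k=3, repeats=1, seed=2)
    train, test = plan.splits[0]
    plan_a = SplitPlan(splits=((train, test),), k=1, repeats=1, seed=0,
                       grouping="subject")
    plan_b = SplitPlan(splits=((train, test[:-2]),), k=1, repeats=1, seed=0,
                       grouping="subject")
    spec = FixedEffectSpec(("class", "age"))
    rep_a = run_evaluation(ds, spec, plan_a, arms=("m0", "lmm"))
    rep_b = run_evaluation(ds, spec, plan_b, arms=("m0", "lmm"))
    pd.testing.assert_series_equal(
        rep_a.per_split.set_index("arm")["n_selected"],
        rep_b.per_split.set_index("arm")["n_selected"])


def test_report_invariant_to_sample_order():
    ds, _ = generate_cohort(CohortConfig(n_subjects=10, n_features=8, seed=10))
    plan = make_splits(ds, k=2, repeats=1, seed=3)
    spec = FixedEffectSpec(("class", "age"))
    rep = run_evaluation(ds, spec, plan, arms=("m0", "lmm"))
    perm = np.random.default_rng(4).permutation(ds.n_samples)
    ds2 = ds.subset_samples(list(np.array(ds.sample_ids)[perm]))
    rep2 = run_evaluation(ds2, spec, plan, arms=("m0", "lmm"))
    pd.testing.assert_frame_equal(rep.per_split, rep2.per_split)


def test_training_fold_missing_class_is_skipped(cohort):
    ds, _ = cohort
    a_ids = tuple(ds.abundances.index[ds.class_label == "A"])
    b_ids = tuple(ds.abundances.index[ds.class_label == "B"])
    good_train = tuple(ds.sample_ids[: ds.n_samples // 2])
    good_test = tuple(ds.sample_ids[ds.n_samples // 2:])
    plan = SplitPlan(splits=((a_ids, b_ids), (good_train, good_test)),
                     k=2, repeats=1, seed=0, grouping="sample")
    rep = run_evaluation(ds, None, plan, arms=("m0",))
    assert len(rep.skipped) == 1 and "missing a class" in rep.skipped[0]
    assert set(rep.per_split["split"]) == {1}


def test_summary_means_match_per_split(cohort):
    ds, _ = cohort
    plan = make_splits(ds, k=3, repeats=2, seed=6)
    rep = run_evaluation(ds, None, plan, arms=("m0", "ml"))
    for arm, g in rep.per_split.groupby("arm"):
        assert rep.summary.loc[arm, ("accuracy", "mean")] == pytest.approx(
            g["accuracy"].mean(), abs=1e-12)
    assert rep.per_split[["accuracy", "precision", "sensitivity",
                          "specificity"]].stack().between(0, 1).all()
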