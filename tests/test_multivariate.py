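import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metlmm import (oplsda_fit, plsda_fit, predict_class,
                    select_discriminative, within_variation)

LABELS8 = np.array(["A", "B"] * 4)


def _random_Xy(seed, n=16, p=6):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    labels = np.array(["A", "B"] * (n // 2))
    return X, labels


def test_single_feature_recovers_indicator():
    y = (LABELS8 == "B").astype(float)
    X = y.reshape(-1, 1) * 2.0 + 5.0
    m = plsda_fit(X, LABELS8, n_components=1, scale=False,
                  class_levels=("A", "B"))
    yc = y - y.mean()
    t = m.scores[:, 0]
    np.testing.assert_allclose(t / np.linalg.norm(t),
                               yc / np.linalg.norm(yc), atol=1e-10)
    np.testing.assert_allclose(m.vip, [1.0], atol=1e-12)


def test_first_weight_matches_svd_oracle():
    X, labels = _random_Xy(0)
    m = plsda_fit(X, labels, n_components=2, scale=False)
    Xc = X - X.mean(axis=0)
    y = (labels == "B").astype(float)
    yc = (y - y.mean()).reshape(-1, 1)
    U, _, _ = np.linalg.svd(Xc.T @ yc, full_matrices=False)
    w_oracle = U[:, 0]
    if np.sign(w_oracle[np.flatnonzero(np.abs(w_oracle) > 1e-12)[0]]) < 0:
        w_oracle = -w_oracle
    np.testing.assert_allclose(m.weights[:, 0], w_oracle, atol=1e-8)


def test_feature_permutation_equivariance():
    X, labels = _random_Xy(1)
    m = plsda_fit(X, labels, n_components=2)
    perm = np.random.default_rng(2).permutation(X.shape[1])
    m2 = plsda_fit(X[:, perm], labels, n_components=2)
    np.testing.assert_allclose(m2.vip, m.vip[perm], atol=1e-10)
    np.testing.assert_allclose(np.abs(m2.weights), np.abs(m.weights[perm]),
                               atol=1e-10)


def test_vip_concentrates_on_signal_feature():
    """Two orthogonal features, one carrying all class signal -> VIP ~
    [sqrt(2), 0]."""
    y = np.array([0, 0, 1, 1], dtype=float)
    X = np.column_stack([y - y.mean(), [1, -1, -1, 1]])  # orthogonal columns
    m = plsda_fit(X, np.where(y == 1, "B", "A"), n_components=1, scale=False,
                  class_levels=("A", "B"))
    np.testing.assert_allclose(m.vip, [np.sqrt(2.0), 0.0], atol=1e-10)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 10_000), st.integers(3, 12), st.integers(1, 3))
def test_mean_squared_vip_is_one(seed, p, ncomp):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(14, p))
    labels = np.array(["A", "B"] * 7)
    m = plsda_fit(X, labels, n_components=ncomp)
    assert np.mean(m.vip ** 2) == pytest.approx(1.0, abs=1e-8)


def test_constant_column_gets_zero_vip_same_scores():
    X, labels = _random_Xy(3)
    m = plsda_fit(X, labels, n_components=2)
    X_aug = np.column_stack([X, np.full(X.shape[0], 9.0)])
    m2 = plsda_fit(X_aug, labels, n_components=2)
    np.testing.assert_allclose(m2.scores, m.scores, atol=1e-10)
    assert m2.vip[-1] == pytest.approx(0.0, abs=1e-12)


def test_scores_mutually_orthogonal():
    X, labels = _random_Xy(4, n=20, p=8)
    m = plsda_fit(X, labels, n_components=3)
    G = m.scores.T @ m.scores
    off = G - np.diag(np.diag(G))
    assert np.abs(off).max() < 1e-8


def test_explained_response_variance_nonincreasing():
    for seed in range(5):
        X, labels = _random_Xy(seed, n=24, p=10)
        m = plsda_fit(X, labels, n_components=4)
        assert np.all(np.diff(m.ss_components) <= 1e-10)


def test_matches_sklearn_pls_scores():
    sk = pytest.importorskip("sklearn.cross_decomposition")
    X, labels = _random_Xy(5, n=18, p=7)
    m = plsda_fit(X, labels, n_components=3, scale=True)
    y = (labels == "B").astype(float)
    ref = sk.PLSRegression(n_components=3, scale=True).fit(X, y - y.mean())
    for a in range(3):
        c = np.corrcoef(m.scores[:, a], ref.x_scores_[:, a])[0, 1]
        assert abs(c) == pytest.approx(1.0, abs=1e-8)


def test_one_class_rejected():
    X = np.random.default_rng(0).normal(size=(6, 3))
    with pytest.raises(ValueError, match="two classes"):
        plsda_fit(X, np.array(["A"] * 6))


def test_oplsda_on_rank_one_signal_equals_plsda():
    """With X aligned to the response there is nothing orthogonal to remove."""
    y = (LABELS8 == "B").astype(float)
    d = y - y.mean()
    X = np.outer(d, [1.0, -2.0, 0.5]) + 10.0
    mo = oplsda_fit(X, LABELS8, n_ortho=1, scale=False)
    mp = plsda_fit(X, LABELS8, n_components=1, scale=False)
    assert float(mo.ortho_scores.var()) == pytest.approx(0.0, abs=1e-16)
    _, so = predict_class(mo, X)
    _, sp = predict_class(mp, X)
    np.testing.assert_allclose(so, sp, atol=1e-8)


def test_oplsda_removes_class_orthogonal_confound():
    """A structured direction uncorrelated with class shifts PLS-DA scores but
    not the OPLS-DA predictive scores."""
    rng = np.random.default_rng(6)
    n, p = 24, 6
    labels = np.array(["A", "B"] * (n // 2))
    y = (labels == "B").astype(float)
    yc = y - y.mean()
    X = np.outer(yc, rng.normal(size=p)) + 0.1 * rng.normal(size=(n, p))
    g = rng.normal(size=n)
    g -= g @ yc / (yc @ yc) * yc          # exactly class-orthogonal
    confound = np.outer(g, rng.normal(size=p)) * 3.0
    X2 = X + confound
    mp1 = plsda_fit(X, labels, n_components=1, scale=False)
    mp2 = plsda_fit(X2, labels, n_components=1, scale=False)
    assert not np.allclose(mp1.scores, mp2.scores, atol=1e-6)
    mo2 = oplsda_fit(X2, labels, n_ortho=1, scale=False)
    # orthogonal scores are exactly uncorrelated with the response
    assert abs(np.corrcoef(mo2.ortho_scores[:, 0], yc)[0, 1]) < 1e-8
    # predictive scores on the confounded matrix match the clean PLS scores
    c = np.corrcoef(mo2.scores[:, 0], mp1.scores[:, 0])[0, 1]
    assert c == pytest.approx(1.0, abs=1e-4)


def test_oplsda_filtering_matches_hand_recursion():
    """The filtered matrix equals X - t_o p_o' with every step of the weight
    recursion transcribed literally."""
    rng = np.random.default_rng(7)
    X = rng.normal(size=(6, 3))
    labels = np.array(["A", "B", "A", "B", "A", "B"])
    m = oplsda_fit(X, labels, n_ortho=1, scale=False)
    # hand transcription
    Xc = X - X.mean(axis=0)
    y = (labels == "B").astype(float)
    yc = y - y.mean()
    w = Xc.T @ yc
    w = w / np.linalg.norm(w)
    t = Xc @ w
    p = Xc.T @ t / (t @ t)
    w_o = p - (w @ p) * w
    w_o = w_o / np.linalg.norm(w_o)
    nz = np.flatnonzero(np.abs(w_o) > 1e-12)
    if w_o[nz[0]] < 0:
        w_o = -w_o
    t_o = Xc @ w_o
    p_o = Xc.T @ t_o / (t_o @ t_o)
    np.testing.assert_allclose(m.ortho_weights[:, 0], w_o, atol=1e-10)
    np.testing.assert_allclose(m.ortho_scores[:, 0], t_o, atol=1e-10)
    Xf = Xc - np.outer(t_o, p_o)
    w2 = Xf.T @ yc
    w2 /= np.linalg.norm(w2)
    np.testing.assert_allclose(np.abs(m.weights[:, 0]), np.abs(w2), atol=1e-10)


# -- multilevel decomposition ---------------------------------------------

def test_within_variation_hand_example():
    X = np.array([[0.0], [2.0], [4.0], [6.0]])
    subjects = ["a", "a", "b", "b"]
    out = within_variation(X, subjects)
    np.testing.assert_allclose(out[:, 0], [2.0, 4.0, 2.0, 4.0])


def test_within_variation_identities():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(12, 4))
    subjects = np.repeat(list("abcdef"), 2)
    out = within_variation(X, subjects)
    grand = X.mean(axis=0)
    for s in "abcdef":
        rows = out[np.array(subjects) == s]
        np.testing.assert_allclose(rows.mean(axis=0), grand, atol=1e-10)
    # idempotent
    np.testing.assert_allclose(within_variation(out, subjects), out, atol=1e-10)


def test_within_variation_singleton_maps_to_grand_mean():
    X = np.array([[1.0, 2.0], [3.0, 4.0], [11.0, 0.0]])
    out = within_variation(X, ["a", "a", "b"])
    np.testing.assert_allclose(out[2], X.mean(axis=0), atol=1e-12)


# -- prediction & selection ------------------------------------------------

def test_predict_reproduces_training_labels_when_separable():
    X, labels = _random_Xy(9)
    X[:, 0] += 10.0 * (labels == "B")
    m = plsda_fit(X, labels, n_components=2)
    pred, _ = predict_class(m, X)
    assert (pred == labels).all()


def test_predict_tie_goes_to_first_class_level():
    y = (LABELS8 == "B").astype(float)
    X = (y - y.mean()).reshape(-1, 1)
    m = plsda_fit(X, LABELS8, n_components=1, scale=False,
                  class_levels=("A", "B"))
    # the grand-mean row scores exactly at the balanced-class threshold
    pred, score = predict_class(m, np.array([[0.0]]) + X.mean())
    assert score[0] == pytest.approx(m.decision_threshold, abs=1e-12)
    assert pred[0] == "A"


def test_predict_missing_feature_named():
    X = pd.DataFrame(np.random.default_rng(1).normal(size=(8, 3)),
                     columns=["f1", "f2", "f3"])
    m = plsda_fit(X, LABELS8, n_components=1)
    with pytest.raises(ValueError, match="f3"):
        predict_class(m, X[["f1", "f2"]])


def test_select_discriminative_rules():
    X, labels = _random_Xy(10)
    m = plsda_fit(X, labels, n_components=2)
    m.vip = np.array([1.2, 0.8, 1.0, 2.0, 0.1, 1.01])
    sel = select_discriminative(m)
    assert list(sel.index) == ["f3", "f0", "f5"]  # descending, strict > 1
    assert select_discriminative(m, threshold=0).size == 6
    m.vip = np.ones(6)
    assert select_discriminative(m).empty
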