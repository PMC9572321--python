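"""LDA/QDA classifiers: closed forms, oracles, invariances, splits."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

import ripegrade as rg
from ripegrade.discriminant import DiscriminantClassifier, SplitConfig, split_indices


def test_1d_toy_lda_boundary_at_zero():
    X = pd.DataFrame({"f": [-2.0, -1.0, 1.0, 2.0]})
    y = np.array(["a", "a", "b", "b"])
    m = DiscriminantClassifier(kind="lda", standardize=False, reg=0).fit(X, y)
    assert m.predict(pd.DataFrame({"f": [0.5]}))[0] == "b"
    assert m.predict(pd.DataFrame({"f": [-0.5]}))[0] == "a"
    s = m.decision_function(pd.DataFrame({"f": [0.0]}))
    assert s[0, 0] == pytest.approx(s[0, 1])


def test_qda_equals_lda_under_equal_covariances():
    rng = np.random.default_rng(0)
    means = np.array([[0.0, 0.0], [3.0, 1.0], [0.0, 4.0]])
    cov = np.array([[1.0, 0.3], [0.3, 0.8]])
    lda = DiscriminantClassifier.from_parameters(
        "lda", ["a", "b", "c"], means, [cov] * 3, [1 / 3] * 3)
    qda = DiscriminantClassifier.from_parameters(
        "qda", ["a", "b", "c"], means, [cov] * 3, [1 / 3] * 3)
    X = rng.normal(0, 3, size=(50, 2))
    np.testing.assert_allclose(lda.predict_proba(X), qda.predict_proba(X),
                               atol=1e-10)


def test_separable_classes_reach_full_training_accuracy(blob_table):
    m = rg.fit_discriminant(blob_table, ["f0", "f1"], kind="qda")
    pred = m.predict(blob_table[["f0", "f1"]])
    assert rg.ccr(rg.confusion(blob_table["class"], pred)) == 100.0


def test_point_at_class_mean_predicts_that_class():
    eye = np.eye(2)
    m = DiscriminantClassifier.from_parameters(
        "lda", ["a", "b"], [[0, 0], [4, 4]], [eye, eye], [0.5, 0.5])
    assert m.predict([[0, 0]])[0] == "a"
    assert m.predict([[4, 4]])[0] == "b"


def test_equidistant_tie_goes_to_earlier_class():
    eye = np.eye(1)
    m = DiscriminantClassifier.from_parameters(
        "lda", ["overripe", "ripe"], [[-1.0], [1.0]], [eye, eye], [0.5, 0.5])
    assert m.predict([[0.0]])[0] == "overripe"


def test_scores_match_independent_density_oracle():
    """Log-posterior scores equal log N(x; mu, Sigma) + log prior computed
    by scipy's multivariate normal (up to the shared constant)."""
    rng = np.random.default_rng(5)
    means = [np.array([0.0, 0.0]), np.array([2.0, -1.0])]
    covs = [np.array([[1.0, 0.2], [0.2, 2.0]]),
            np.array([[0.5, 0.0], [0.0, 0.7]])]
    priors = [0.3, 0.7]
    m = DiscriminantClassifier.from_parameters("qda", ["a", "b"], means, covs, priors)
    X = rng.normal(size=(20, 2))
    s = m.decision_function(X)
    for c in range(2):
        oracle = sps.multivariate_normal(means[c], covs[c]).logpdf(X) \
            + np.log(priors[c])
        np.testing.assert_allclose(s[:, c] - s[:, 0],
                                   oracle - (sps.multivariate_normal(
                                       means[0], covs[0]).logpdf(X) + np.log(priors[0])),
                                   atol=1e-9)


def test_agrees_with_sklearn_lda(blob_table):
    X = blob_table[["f0", "f1"]].to_numpy()
    y = blob_table["class"].to_numpy()
    ours = DiscriminantClassifier(kind="lda", standardize=False, reg=0).fit(X, y)
    ref = LinearDiscriminantAnalysis().fit(X, y)
    rng = np.random.default_rng(1)
    grid = rng.uniform(-2, 8, size=(200, 2))
    assert (ours.predict(grid) == ref.predict(grid)).mean() > 0.99


def test_affine_feature_rescaling_invariance(blob_table):
    Xdf = blob_table[["f0", "f1"]]
    y = blob_table["class"].to_numpy()
    a = DiscriminantClassifier(kind="qda").fit(Xdf.to_numpy(), y)
    scaled = Xdf.to_numpy() * np.array([100.0, 0.01]) + np.array([5.0, -3.0])
    b = DiscriminantClassifier(kind="qda").fit(scaled, y)
    probe = Xdf.to_numpy()[::7]
    probe_scaled = probe * np.array([100.0, 0.01]) + np.array([5.0, -3.0])
    np.testing.assert_allclose(a.predict_proba(probe),
                               b.predict_proba(probe_scaled), atol=1e-8)


def test_duplicating_samples_leaves_model_unchanged(blob_table):
    X = blob_table[["f0", "f1"]].to_numpy()
    y = blob_table["class"].to_numpy()
    a = DiscriminantClassifier(kind="lda").fit(X, y)
    b = DiscriminantClassifier(kind="lda").fit(np.vstack([X, X]),
                                               np.concatenate([y, y]))
    np.testing.assert_allclose(a.means_, b.means_, atol=1e-10)
    # pooled covariance differs only through the ddof correction
    np.testing.assert_allclose(a.covariance_, b.covariance_, rtol=0.05)
    grid = np.random.default_rng(0).uniform(-2, 8, size=(50, 2))
    assert (a.predict(grid) == b.predict(grid)).all()


def test_singular_covariance_without_reg_raises():
    X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])  # rank 1
    y = np.array(["a", "a", "b", "b"])
    with pytest.raises(np.linalg.LinAlgError, match="reg"):
        DiscriminantClassifier(kind="lda", reg=0.0).fit(X, y)
    DiscriminantClassifier(kind="lda", reg=1e-6).fit(X, y)  # regularized: fine


def test_missing_feature_column_rejected(blob_table):
    m = rg.fit_discriminant(blob_table, ["f0", "f1"], kind="lda")
    with pytest.raises(ValueError, match="missing feature"):
        m.decision_function(blob_table[["f0"]])


def test_json_round_trip(blob_table):
    m = rg.fit_discriminant(blob_table, ["f0", "f1"], kind="qda")
    clone = DiscriminantClassifier.from_dict(m.to_dict())
    X = blob_table[["f0", "f1"]]
    np.testing.assert_allclose(m.decision_function(X),
                               clone.decision_function(X), atol=1e-12)


def test_predict_discriminant_single_sample(blob_table):
    m = rg.fit_discriminant(blob_table, ["f0", "f1"], kind="lda")
    label, scores = rg.predict_discriminant(m, {"f0": 6.0, "f1": 6.0})
    assert label == "initial_unripe"  # the (6, 6) blob
    assert set(scores) == set(rg.CLASS_ORDER)


class TestSplits:
    def test_80_20_stratified_counts(self):
        y = np.repeat(rg.CLASS_ORDER, 40)
        tr, te = split_indices(y, SplitConfig(ratios=(0.8, 0.2), seed=0))
        assert len(tr) == 128 and len(te) == 32
        for c in rg.CLASS_ORDER:
            assert (y[te] == c).sum() == 8

    def test_60_20_20_stratified_counts(self):
        y = np.repeat(rg.CLASS_ORDER, 40)
        tr, va, te = split_indices(
            y, SplitConfig(ratios=(0.6, 0.2, 0.2), seed=0))
        assert len(tr) == 96 and len(va) == 32 and len(te) == 32
        assert len(set(tr) | set(va) | set(te)) == 160

    def test_invalid_ratios_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            SplitConfig(ratios=(0.8, 0.1))
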