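"""Standardization, PCA reduction, splitting and SVM evaluation."""

import numpy as np
import pandas as pd
import pytest

from padeeg import (
    KernelSpec,
    SplitSpec,
    ValidationError,
    reduce_pca,
    split_cohort,
    standardize,
    train_and_evaluate,
)
from padeeg.classify import apply_pca, apply_standardize
from padeeg.eeg import BAND_NAMES


def feature_frame(X):
    X = np.asarray(X, dtype=float)
    cols = list(BAND_NAMES)[: X.shape[1]]
    return pd.DataFrame(X, columns=cols)


# ------------------------------------------------------------ standardize

def test_standardize_simple_column():
    Xs, _ = standardize(feature_frame([[1.0], [2.0], [3.0]]))
    assert Xs.iloc[:, 0].tolist() == [-1.0, 0.0, 1.0]


def test_constant_column_centered_with_warning():
    with pytest.warns(UserWarning, match="zero-variance"):
        Xs, _ = standardize(feature_frame([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]))
    assert np.allclose(Xs.iloc[:, 0], 0.0)


def test_standardize_round_trip():
    X = feature_frame(np.random.default_rng(0).normal(size=(10, 3)))
    Xs, params = standardize(X)
    back = Xs.to_numpy() * params.sd + params.mean
    assert np.allclose(back, X.to_numpy(), atol=1e-12)


def test_standardize_needs_two_rows():
    with pytest.raises(ValidationError):
        standardize(feature_frame([[1.0, 2.0]]))


# ------------------------------------------------------------------- PCA

def test_full_variance_target_reconstructs_input(rng):
    X = feature_frame(rng.normal(size=(20, 4)))
    Xs, _ = standardize(X)
    Z, params = reduce_pca(Xs, variance_target=1.0)
    recon = Z.to_numpy() @ params.components + params.mean
    assert np.allclose(recon, Xs.to_numpy(), atol=1e-10)


def test_rank_one_data_keeps_single_component(rng):
    base = rng.normal(size=20)
    X = feature_frame(np.column_stack([base, 2 * base, -0.5 * base]))
    Z, params = reduce_pca(X, variance_target=0.95)
    assert params.components.shape[0] == 1


def test_explained_variance_ratios_conserved(rng):
    X = feature_frame(rng.normal(size=(30, 5)))
    _, params = reduce_pca(X, variance_target=1.0)
    assert params.explained_variance_ratio.sum() == pytest.approx(1.0)


def test_invalid_variance_target_rejected(rng):
    X = feature_frame(rng.normal(size=(5, 2)))
    with pytest.raises(ValidationError):
        reduce_pca(X, variance_target=0.0)


# ----------------------------------------------------------------- split

def test_split_sizes_for_42_visitors():
    labels = ["negative"] * 28 + ["positive"] * 14
    train, test = split_cohort(labels, SplitSpec(seed=7))
    assert train.size == 29  # test size = ceil(0.3 * 42) = 13
    assert test.size == 13


def test_split_deterministic_and_partitioning():
    labels = ["negative"] * 20 + ["positive"] * 10
    spec = SplitSpec(seed=11)
    t1 = split_cohort(labels, spec)
    t2 = split_cohort(labels, spec)
    assert (t1[0] == t2[0]).all() and (t1[1] == t2[1]).all()
    union = np.sort(np.concatenate(t1))
    assert (union == np.arange(30)).all()


def test_stratified_class_fractions_within_one_sample():
    labels = np.array(["negative"] * 28 + ["positive"] * 14)
    train, _ = split_cohort(labels, SplitSpec(seed=3))
    for cls, n_cls in (("negative", 28), ("positive", 14)):
        n_train = int((labels[train] == cls).sum())
        assert abs(n_train - 0.7 * n_cls) <= 1.0


def test_split_requires_both_classes_and_min_members():
    with pytest.raises(ValidationError):
        split_cohort(["positive"] * 10, SplitSpec())
    with pytest.raises(ValidationError):
        split_cohort(["positive"] + ["negative"] * 9, SplitSpec())


# -------------------------------------------------------------- training

def separable_cohort(n=40, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 5))
    y = np.array(["positive"] * (n // 2) + ["negative"] * (n - n // 2))
    X[y == "positive", 3] += 8.0  # beta column cleanly separates the classes
    return feature_frame(X), y


def test_separable_classes_reach_perfect_recall():
    X, y = separable_cohort()
    split = split_cohort(y, SplitSpec(seed=1))
    rep = train_and_evaluate(X, y, split, (KernelSpec("linear"),))
    for part in ("train", "test"):
        for cls in ("positive", "negative"):
            assert rep.rates["linear"][part][cls] == 1.0


def test_report_layout_covers_kernels_classes_partitions():
    X, y = separable_cohort()
    split = split_cohort(y, SplitSpec(seed=1))
    rep = train_and_evaluate(X, y, split)
    assert set(rep.rates) == {"linear", "polynomial", "gaussian", "sigmoid"}
    for kernel in rep.rates:
        assert set(rep.rates[kernel]) == {"train", "test"}
        for part in ("train", "test"):
            assert set(rep.rates[kernel][part]) == {"positive", "negative"}
    text = rep.to_text()
    assert "linear" in text and "sigmoid" in text


def test_failure_marker_when_class_never_predicted(rng):
    # heavy imbalance + uninformative features: SVM predicts only the majority
    X = feature_frame(rng.normal(size=(40, 5)))
    y = np.array(["positive"] * 4 + ["negative"] * 36)
    split = split_cohort(y, SplitSpec(seed=5))
    rep = train_and_evaluate(X, y, split, (KernelSpec("linear"),))
    assert rep.rates["linear"]["test"]["positive"] is None
    assert "–" in rep.to_text()


def test_single_class_training_partition_rejected():
    X, y = separable_cohort(n=10)
    bad_split = (np.arange(5), np.arange(5, 10))  # train rows all positive
    with pytest.raises(ValidationError):
        train_and_evaluate(X, y, bad_split, (KernelSpec("linear"),))


def test_no_leakage_from_test_rows():
    # perturbing a test-partition row must not change train-side results
    X, y = separable_cohort(seed=4)
    split = split_cohort(y, SplitSpec(seed=2))
    rep1 = train_and_evaluate(X, y, split)
    X2 = X.copy()
    X2.iloc[split[1][0]] += 100.0
    rep2 = train_and_evaluate(X2, y, split)
    assert rep1.n_components == rep2.n_components
    for kernel in rep1.rates:
        assert rep1.rates[kernel]["train"] == rep2.rates[kernel]["train"]
        assert rep1.accuracy[kernel]["train"] == rep2.accuracy[kernel]["train"]


def test_pipeline_deterministic_given_seed():
    X, y = separable_cohort(seed=9)
    split = split_cohort(y, SplitSpec(seed=9))
    rep1 = train_and_evaluate(X, y, split)
    rep2 = train_and_evaluate(X, y, split)
    assert rep1.rates == rep2.rates and rep1.accuracy == rep2.accuracy


def test_kernel_spec_validation():
    with pytest.raises(ValidationError):
        KernelSpec("quadratic")
    with pytest.raises(ValidationError):
        KernelSpec("polynomial", degree=0)
    with pytest.raises(ValidationError):
        KernelSpec("gaussian", c=-1.0)
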