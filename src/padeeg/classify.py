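"""Positive/negative tendency classification from band-energy features.

Pipeline: column standardization (fit on training rows), PCA retaining a
target fraction of variance (fit on training rows), and support-vector
machines with linear, polynomial, Gaussian (RBF) and sigmoid kernels.
Per-class "success rates" are recalls — the fraction of samples truly in a
class that the classifier assigns to that class — reported separately for
the training and test partitions. A kernel that assigns no sample to some
class gets a failure marker for that class instead of a rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .eeg import BAND_NAMES
from .emotions import ValidationError

__all__ = [
    "SplitSpec",
    "KernelSpec",
    "StandardizeParams",
    "PCAParams",
    "ClassifierReport",
    "DEFAULT_KERNELS",
    "standardize",
    "apply_standardize",
    "reduce_pca",
    "apply_pca",
    "split_cohort",
    "train_and_evaluate",
]

CLASSES = ("positive", "negative")


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition policy: test size is ceil((1 - train_fraction) * n)."""

    train_fraction: float = 0.7
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValidationError("train_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class KernelSpec:
    """SVM kernel configuration.

    ``gamma`` follows the 1/(n_features * feature variance) convention when
    left as 'scale'; ``c`` is the soft-margin regularization weight.
    """

    kind: str
    degree: int = 3
    gamma: float | str = "scale"
    c: float = 1.0

    _SKLEARN = {"linear": "linear", "polynomial": "poly",
                "gaussian": "rbf", "sigmoid": "sigmoid"}

    def __post_init__(self) -> None:
        if self.kind not in self._SKLEARN:
            raise ValidationError(
                f"kernel kind {self.kind!r} not one of {sorted(self._SKLEARN)}"
            )
        if self.degree < 1:
            raise ValidationError("polynomial degree must be >= 1")
        if isinstance(self.gamma, float) and self.gamma <= 0:
            raise ValidationError("kernel width must be positive")
        if self.c <= 0:
            raise ValidationError("regularization weight must be positive")

    def build(self) -> SVC:
        return SVC(kernel=self._SKLEARN[self.kind], degree=self.degree,
                   gamma=self.gamma, C=self.c)


DEFAULT_KERNELS = (
    KernelSpec("linear"),
    KernelSpec("polynomial"),
    KernelSpec("gaussian"),
    KernelSpec("sigmoid"),
)


@dataclass(frozen=True)
class StandardizeParams:
    mean: np.ndarray
    sd: np.ndarray  # n-1 convention; zero-variance columns get sd 1 (centering only)


def standardize(features: pd.DataFrame) -> tuple[pd.DataFrame, StandardizeParams]:
    """Scale each column to mean 0, sd 1 (sample sd, n-1 denominator).

    Zero-variance columns are passed through centered, with a warning.
    Returns the fitted parameters for reuse on held-out rows.
    """
    X = features.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 rows to standardize")
    if np.isnan(X).any():
        raise ValidationError("feature matrix contains missing entries")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        import warnings

        cols = list(features.columns[degenerate])
        warnings.warn(f"zero-variance feature columns centered only: {cols}")
        sd = np.where(degenerate, 1.0, sd)
    params = StandardizeParams(mean=mean, sd=sd)
    return apply_standardize(features, params), params


def apply_standardize(
    features: pd.DataFrame, params: StandardizeParams
) -> pd.DataFrame:
    X = (features.to_numpy(dtype=float) - params.mean) / params.sd
    return pd.DataFrame(X, index=features.index, columns=features.columns)


@dataclass(frozen=True)
class PCAParams:
    components: np.ndarray  # (k, n_features) loadings
    mean: np.ndarray
    explained_variance_ratio: np.ndarray


def reduce_pca(
    features: pd.DataFrame, variance_target: float = 0.95
) -> tuple[pd.DataFrame, PCAParams]:
    """Project onto the smallest leading PC set explaining >= variance_target.

    Fit on the rows given (training rows); apply to held-out rows with
    :func:`apply_pca` so no test information leaks into the loadings.
    """
    if not 0.0 < variance_target <= 1.0:
        raise ValidationError("variance_target must lie in (0, 1]")
    pca = PCA().fit(features.to_numpy(dtype=float))
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    k = min(k, pca.components_.shape[0])
    params = PCAParams(
        components=pca.components_[:k],
        mean=pca.mean_,
        explained_variance_ratio=pca.explained_variance_ratio_[:k],
    )
    return apply_pca(features, params), params


def apply_pca(features: pd.DataFrame, params: PCAParams) -> pd.DataFrame:
    Z = (features.to_numpy(dtype=float) - params.mean) @ params.components.T
    cols = [f"pc{i + 1}" for i in range(params.components.shape[0])]
    return pd.DataFrame(Z, index=features.index, columns=cols)


def split_cohort(
    labels: Sequence[str], spec: SplitSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic (seeded) train/test split of visitor indices.

    With stratification, per-class train fractions are within one sample of
    ``train_fraction``; a class needs at least 2 members to stratify.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValidationError("both tendency classes must be present to split")
    if spec.stratified and counts.min() < 2:
        raise ValidationError(
            "stratified split needs at least 2 members per class"
        )
    idx = np.arange(y.size)
    train, test = train_test_split(
        idx,
        test_size=1.0 - spec.train_fraction,
        stratify=y if spec.stratified else None,
        random_state=spec.seed,
    )
    return np.sort(train), np.sort(test)


@dataclass(frozen=True)
class ClassifierReport:
    """Per-kernel, per-class, per-partition success rates (recalls).

    ``rates[kernel][partition][cls]`` is a float in [0, 1] or None when the
    kernel predicted no sample of that class (the failure marker, printed
    as an en-dash). ``accuracy[kernel][partition]`` is overall accuracy.
    """

    rates: Mapping[str, Mapping[str, Mapping[str, float | None]]]
    accuracy: Mapping[str, Mapping[str, float]]
    n_components: int
    split_sizes: tuple[int, int]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for kernel, parts in self.rates.items():
            row = {"method": kernel}
            for cls in CLASSES:
                for part in ("train", "test"):
                    v = parts[part][cls]
                    row[f"{cls}_{part}"] = v
            rows.append(row)
        return pd.DataFrame(rows).set_index("method")

    def to_text(self) -> str:
        lines = [
            "Success rates of support-vector-machine tendency classification",
            f"(train n={self.split_sizes[0]}, test n={self.split_sizes[1]}, "
            f"{self.n_components} principal component(s))",
            "",
            f"{'Method':<22}{'Positive class':^24}{'Negative class':^24}",
            f"{'':<22}{'Train':^12}{'Test':^12}{'Train':^12}{'Test':^12}",
        ]
        for kernel, parts in self.rates.items():
            cells = []
            for cls in CLASSES:
                for part in ("train", "test"):
                    v = parts[part][cls]
                    cells.append("–" if v is None else f"{v:.3f}")
            lines.append(
                f"{kernel:<22}" + "".join(f"{c:^12}" for c in cells)
            )
        return "\n".join(lines)


def _per_class_rates(
    y_true: np.ndarray, y_pred: np.ndarray
) -> dict[str, float | None]:
    out: dict[str, float | None] = {}
    for cls in CLASSES:
        if not np.any(y_pred == cls) and np.any(y_true == cls):
            out[cls] = None  # kernel never predicts this class
            continue
        mask = y_true == cls
        out[cls] = float(np.mean(y_pred[mask] == cls)) if mask.any() else None
    return out


def train_and_evaluate(
    features: pd.DataFrame,
    labels: Sequence[str],
    split: tuple[np.ndarray, np.ndarray],
    kernels: Sequence[KernelSpec] = DEFAULT_KERNELS,
    variance_target: float = 0.95,
) -> ClassifierReport:
    """Fit each kernel on the training rows and report per-class recalls.

    Standardization and PCA are fitted on the training rows only and then
    applied to the test rows.
    """
    if not kernels:
        raise ValidationError("need at least one kernel")
    train_idx, test_idx = split
    y = np.asarray(labels)
    if np.unique(y[train_idx]).size < 2:
        raise ValidationError("training partition contains a single class")

    X_train = features.iloc[train_idx]
    X_test = features.iloc[test_idx]
    X_train_s, scale_params = standardize(X_train)
    X_test_s = apply_standardize(X_test, scale_params)
    Z_train, pca_params = reduce_pca(X_train_s, variance_target)
    Z_test = apply_pca(X_test_s, pca_params)

    rates: dict[str, dict[str, dict[str, float | None]]] = {}
    accuracy: dict[str, dict[str, float]] = {}
    for spec in kernels:
        clf = spec.build().fit(Z_train.to_numpy(), y[train_idx])
        pred_train = clf.predict(Z_train.to_numpy())
        pred_test = clf.predict(Z_test.to_numpy())
        rates[spec.kind] = {
            "train": _per_class_rates(y[train_idx], pred_train),
            "test": _per_class_rates(y[test_idx], pred_test),
        }
        accuracy[spec.kind] = {
            "train": float(np.mean(pred_train == y[train_idx])),
            "test": float(np.mean(pred_test == y[test_idx])),
        }
    return ClassifierReport(
        rates=rates,
        accuracy=accuracy,
        n_components=pca_params.components.shape[0],
        split_sizes=(train_idx.size, test_idx.size),
    )
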