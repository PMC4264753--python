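"""L1-regularized multinomial classification of growth environments from fluxes.

The estimator follows the GLMNET recipe for ``family = "multinomial"`` with
``alpha = 1`` (pure LASSO): features are standardized, a decreasing penalty
path is generated from the smallest lambda that zeroes every coefficient, the
model is fit by warm-started solves along the path, and the selected lambda is
the one minimizing cross-validated misclassification (no one-standard-error
rule). At the selected penalty most coefficients are exactly zero; the
surviving reactions are the *predictive fluxes*.

Prediction runs in three modes: ``joint`` (one classifier over all
carbon x nitrogen pairs), and ``separate_C`` / ``separate_N`` (one classifier
per axis, combined by pairing — a joint prediction is correct only when both
axes are).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .simulate import FluxDataset

__all__ = [
    "ClassifierConfig",
    "L1MultinomialLogisticCV",
    "TrainedClassifier",
    "build_features",
    "train",
    "predict",
    "combine_separate",
    "JOINT_SEP",
]

#: separator used to join carbon and nitrogen ids into a joint class label
JOINT_SEP = "|"

FLUX_ZERO_THRESHOLD = 1e-6


@dataclass
class ClassifierConfig:
    """Fitting configuration; alpha is fixed at 1 (LASSO), not exposed."""

    mode: str = "joint"  # {"joint", "separate_C", "separate_N"}
    n_folds: int = 3
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    lambda_path: list[float] | None = None
    flux_zero_threshold: float = FLUX_ZERO_THRESHOLD
    standardize: bool = True
    tol: float = 1e-3
    max_iter: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("joint", "separate_C", "separate_N"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.lambda_path is not None:
            lp = np.asarray(self.lambda_path, dtype=float)
            if lp.ndim != 1 or len(lp) == 0 or np.any(np.diff(lp) >= 0):
                raise ValueError("lambda_path must be strictly decreasing")


class L1MultinomialLogisticCV(BaseEstimator, ClassifierMixin):
    """Multinomial logistic regression with an L1 penalty path and CV selection.

    Parameters
    ----------
    n_lambda : int
        Length of the auto-generated penalty path.
    lambda_min_ratio : float
        Smallest path value as a fraction of lambda_max (the penalty at which
        all coefficients are zero).
    lambda_path : array-like, optional
        Explicit strictly decreasing path; overrides the two parameters above.
    n_folds : int
        Stratified cross-validation folds for penalty selection.
    standardize : bool
        Center and scale features before fitting; coefficients are reported on
        the standardized scale.
    tol, max_iter : float, int
        Convergence control for the saga solver.
    random_state : int, optional
        Seeds fold assignment and the solver; the fit is deterministic given it.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels.
    coef_ : ndarray, (n_classes, n_features) or (1, n_features) for 2 classes
        Sparse coefficient matrix at the selected penalty (standardized scale).
    intercept_ : ndarray
    lambda_path_ : ndarray
    cv_misclassification_ : ndarray
        Mean held-out misclassification per path value.
    lambda_selected_ : float
    """

    def __init__(
        self,
        n_lambda: int = 100,
        lambda_min_ratio: float = 1e-4,
        lambda_path=None,
        n_folds: int = 3,
        standardize: bool = True,
        tol: float = 1e-3,
        max_iter: int = 1000,
        random_state: int | None = None,
    ):
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.lambda_path = lambda_path
        self.n_folds = n_folds
        self.standardize = standardize
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _transform(self, X: np.ndarray) -> np.ndarray:
        if not self.standardize:
            return X
        return (X - self.means_) / self.scales_

    def _lambda_max(self, Xs: np.ndarray, y_enc: np.ndarray, k: int) -> float:
        n = len(y_enc)
        Y = np.eye(k)[y_enc]
        resid = Y - Y.mean(axis=0)
        return float(np.abs(Xs.T @ resid).max() / n)

    def _path_fit(self, Xs, y, path, n_obs):
        """Warm-started saga fits along a decreasing penalty path."""
        est = LogisticRegression(
            l1_ratio=1.0,
            solver="saga",
            warm_start=True,
            tol=self.tol,
            max_iter=self.max_iter,
            random_state=self.random_state,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for lam in path:
                est.C = 1.0 / (n_obs * lam)
                est.fit(Xs, y)
                yield est

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per label")
        self.n_features_in_ = X.shape[1]

        self.classes_, y_enc = np.unique(y, return_inverse=True)
        k = len(self.classes_)
        if k < 2:
            raise ValueError("need at least 2 classes to train a classifier")
        counts = np.bincount(y_enc, minlength=k)
        loo = self.n_folds >= len(y_enc)  # n_folds = n requests leave-one-out
        min_count = 2 if loo else self.n_folds
        starved = [str(c) for c, m in zip(self.classes_, counts) if m < min_count]
        if starved:
            raise ValueError(
                f"classes with fewer than {min_count} observations "
                f"(untrainable at n_folds={self.n_folds}): {starved}"
            )

        if self.standardize:
            self.means_ = X.mean(axis=0)
            scales = X.std(axis=0)
            self.scales_ = np.where(scales > 0, scales, 1.0)
        else:
            self.means_ = np.zeros(X.shape[1])
            self.scales_ = np.ones(X.shape[1])
        Xs = self._transform(X)

        if self.lambda_path is not None:
            path = np.asarray(self.lambda_path, dtype=float)
            if np.any(np.diff(path) >= 0):
                raise ValueError("lambda_path must be strictly decreasing")
        else:
            lam_max = max(self._lambda_max(Xs, y_enc, k), 1e-12)
            path = np.geomspace(lam_max, lam_max * self.lambda_min_ratio, self.n_lambda)
        self.lambda_path_ = path

        if loo:
            splits = [(np.delete(np.arange(len(y_enc)), i), np.array([i]))
                      for i in range(len(y_enc))]
        else:
            skf = StratifiedKFold(
                n_splits=self.n_folds, shuffle=True, random_state=self.random_state
            )
            splits = list(skf.split(Xs, y_enc))
        errs = np.empty((len(path), len(splits)))
        for f, (tr, va) in enumerate(splits):
            for li, est in enumerate(self._path_fit(Xs[tr], y_enc[tr], path, len(tr))):
                errs[li, f] = float(np.mean(est.predict(Xs[va]) != y_enc[va]))
        self.cv_misclassification_ = errs.mean(axis=1)

        # ties resolved toward the larger (sparser) penalty: first minimum
        i_sel = int(np.argmin(self.cv_misclassification_))
        self.lambda_selected_ = float(path[i_sel])
        for est in self._path_fit(Xs, y_enc, path[: i_sel + 1], len(y_enc)):
            pass
        self.coef_ = est.coef_.copy()
        self.intercept_ = est.intercept_.copy()
        return self

    def decision_function(self, X) -> np.ndarray:
        """Per-class linear scores, shape (n_obs, n_classes)."""
        check_is_fitted(self, "coef_")
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        Xs = self._transform(np.asarray(X, dtype=float))
        z = Xs @ self.coef_.T + self.intercept_
        if len(self.classes_) == 2 and z.shape[1] == 1:
            z = np.hstack([-z, z])  # binary fit stores a single contrast
        return z

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        # np.argmax takes the first maximum: ties break toward class order
        return self.classes_[np.argmax(scores, axis=1)]

    def nonzero_features(self) -> dict:
        """Indices of nonzero coefficients per class at the selected penalty."""
        check_is_fitted(self, "coef_")
        if len(self.classes_) == 2 and self.coef_.shape[0] == 1:
            idx = np.flatnonzero(self.coef_[0])
            return {c: idx for c in self.classes_}
        return {
            c: np.flatnonzero(self.coef_[i]) for i, c in enumerate(self.classes_)
        }


@dataclass
class TrainedClassifier:
    """A fitted model plus the metadata needed to apply and serialize it."""

    mode: str
    feature_ids: list[str]
    estimator: L1MultinomialLogisticCV
    config: ClassifierConfig | None = field(default=None, repr=False)

    @property
    def classes(self) -> list:
        return list(self.estimator.classes_)

    @property
    def coefficients(self) -> np.ndarray:
        return self.estimator.coef_

    @property
    def intercepts(self) -> np.ndarray:
        return self.estimator.intercept_

    @property
    def lambda_selected(self) -> float:
        return self.estimator.lambda_selected_

    @property
    def cv_misclassification(self) -> np.ndarray:
        return self.estimator.cv_misclassification_

    def to_json(self, path: str | Path | None = None) -> str:
        est = self.estimator
        coef = est.coef_
        triplets = [
            [int(i), int(j), float(coef[i, j])] for i, j in zip(*np.nonzero(coef))
        ]
        doc = {
            "mode": self.mode,
            "feature_ids": list(self.feature_ids),
            "classes": [str(c) for c in est.classes_],
            "coef_shape": list(coef.shape),
            "coef_triplets": triplets,
            "intercepts": est.intercept_.tolist(),
            "means": est.means_.tolist(),
            "scales": est.scales_.tolist(),
            "standardize": est.standardize,
            "lambda_selected": est.lambda_selected_,
            "lambda_path": est.lambda_path_.tolist(),
            "cv_misclassification": est.cv_misclassification_.tolist(),
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TrainedClassifier":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        doc = json.loads(text)
        est = L1MultinomialLogisticCV(standardize=doc["standardize"])
        est.classes_ = np.asarray(doc["classes"], dtype=object)
        coef = np.zeros(doc["coef_shape"])
        for i, j, v in doc["coef_triplets"]:
            coef[i, j] = v
        est.coef_ = coef
        est.intercept_ = np.asarray(doc["intercepts"])
        est.means_ = np.asarray(doc["means"])
        est.scales_ = np.asarray(doc["scales"])
        est.lambda_selected_ = doc["lambda_selected"]
        est.lambda_path_ = np.asarray(doc["lambda_path"])
        est.cv_misclassification_ = np.asarray(doc["cv_misclassification"])
        est.n_features_in_ = len(doc["feature_ids"])
        return cls(mode=doc["mode"], feature_ids=doc["feature_ids"], estimator=est)

    def coefficient_table(self) -> pd.DataFrame:
        """Tidy (class, reaction, coefficient) table of nonzero coefficients."""
        rows = []
        nz = self.estimator.nonzero_features()
        coef = self.estimator.coef_
        binary_contrast = len(self.classes) == 2 and coef.shape[0] == 1
        for i, c in enumerate(self.classes):
            row = coef[0] if binary_contrast else coef[i]
            for j in nz[c]:
                rows.append({"class": c, "reaction": self.feature_ids[j], "coefficient": row[j]})
        return pd.DataFrame(rows, columns=["class", "reaction", "coefficient"])


def build_features(
    dataset: FluxDataset,
    config: ClassifierConfig,
    restrict_to: set[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature matrix and labels for a given prediction mode.

    Flux magnitudes below ``config.flux_zero_threshold`` are set to exactly
    zero (numerical noise from the LP solver would otherwise masquerade as
    signal and hamper LASSO convergence). ``restrict_to`` keeps only the named
    reaction columns, e.g. for a post-transport-only model.
    """
    X = dataset.X.copy()
    X = X.mask(X.abs() < config.flux_zero_threshold, 0.0)
    if restrict_to is not None:
        keep = [c for c in X.columns if c in set(restrict_to)]
        if not keep:
            raise ValueError("restrict_to shares no reactions with the dataset columns")
        X = X[keep]
    if config.mode == "joint":
        labels = dataset.joint_labels().to_numpy()
    elif config.mode == "separate_C":
        labels = dataset.carbon_labels.to_numpy()
    else:
        labels = dataset.nitrogen_labels.to_numpy()
    return X, labels


def train(features: pd.DataFrame, labels, config: ClassifierConfig) -> TrainedClassifier:
    """Fit an L1 multinomial classifier with CV penalty selection."""
    est = L1MultinomialLogisticCV(
        n_lambda=config.n_lambda,
        lambda_min_ratio=config.lambda_min_ratio,
        lambda_path=config.lambda_path,
        n_folds=config.n_folds,
        standardize=config.standardize,
        tol=config.tol,
        max_iter=config.max_iter,
        random_state=config.seed,
    )
    est.fit(features, np.asarray(labels))
    return TrainedClassifier(
        mode=config.mode,
        feature_ids=list(features.columns),
        estimator=est,
        config=config,
    )


def predict(classifier: TrainedClassifier, features: pd.DataFrame) -> np.ndarray:
    """Hard-label prediction; feature columns must match the training columns."""
    if list(features.columns) != list(classifier.feature_ids):
        raise ValueError("feature columns do not match classifier.feature_ids")
    return classifier.estimator.predict(features)


def combine_separate(pred_C, pred_N) -> np.ndarray:
    """Pair separate-axis predictions into joint labels (correct iff both are)."""
    pred_C, pred_N = np.asarray(pred_C), np.asarray(pred_N)
    if pred_C.shape != pred_N.shape:
        raise ValueError(
            f"prediction lengths differ: {pred_C.shape} vs {pred_N.shape}"
        )
    return np.array([f"{c}{JOINT_SEP}{n}" for c, n in zip(pred_C, pred_N)])
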