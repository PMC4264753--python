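"""Evaluation of inverse environment prediction.

Covers test-set scoring (misclassification rates and per-axis confusion
matrices), the random-guess baseline, extraction of predictive reactions from
the fitted LASSO coefficients, single-reaction ablation, the unseen-substrate
extrapolation protocol, and k-means selection of maximally distinct substrates
from impurity-free flux profiles.

"Combined" misclassification for separate-mode prediction is counted at the
observation level: an observation is correct only when both its carbon and its
nitrogen prediction are correct, so overlapping per-axis errors are never
double-counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .classify import (
    ClassifierConfig,
    TrainedClassifier,
    build_features,
    combine_separate,
    predict,
    train,
)
from .simulate import FluxDataset

__all__ = [
    "EvaluationReport",
    "PredictiveReactionSet",
    "score",
    "random_guess_rate",
    "predictive_reactions",
    "combine_predictive_sets",
    "ablation_study",
    "novel_substrate_protocol",
    "select_distinct_substrates",
]


def _confusion(actual, predicted, classes) -> pd.DataFrame:
    """Count matrix with actual classes as columns, predicted as rows."""
    classes = list(classes)
    df = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for a, p in zip(actual, predicted):
        if p not in df.index:
            df.loc[p] = 0
        df.loc[p, a] += 1
    return df


def normalize_confusion(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-actual-class frequencies: each column sums to 1 (heat-map data)."""
    totals = counts.sum(axis=0).replace(0, 1)
    return counts / totals


@dataclass
class EvaluationReport:
    """Misclassification rates and confusion matrices for one scenario."""

    mode: str
    n_test: int
    misclassification_rate: float
    rate_C: float | None = None
    rate_N: float | None = None
    confusion_C: pd.DataFrame | None = None
    confusion_N: pd.DataFrame | None = None
    confusion_joint: pd.DataFrame | None = None
    n_mispredictions: int = 0
    metadata: dict = field(default_factory=dict)


def score(
    test: FluxDataset,
    classifiers: TrainedClassifier | tuple[TrainedClassifier, TrainedClassifier],
    config: ClassifierConfig,
) -> EvaluationReport:
    """Score a joint classifier or a (carbon, nitrogen) pair on a test set.

    For separate mode pass ``(clf_C, clf_N)``; the combined rate is the
    fraction of observations with at least one wrong axis.
    """
    if test.n_obs == 0:
        raise ValueError("test dataset is empty")
    if isinstance(classifiers, TrainedClassifier):
        X, labels = build_features(test, replace(config, mode="joint"))
        pred = predict(classifiers, X[classifiers.feature_ids])
        wrong = pred != labels
        return EvaluationReport(
            mode="joint",
            n_test=test.n_obs,
            misclassification_rate=float(wrong.mean()),
            confusion_joint=_confusion(labels, pred, classifiers.classes),
            n_mispredictions=int(wrong.sum()),
        )

    clf_C, clf_N = classifiers
    X_C, y_C = build_features(test, replace(config, mode="separate_C"))
    X_N, y_N = build_features(test, replace(config, mode="separate_N"))
    pred_C = predict(clf_C, X_C[clf_C.feature_ids])
    pred_N = predict(clf_N, X_N[clf_N.feature_ids])
    joint_pred = combine_separate(pred_C, pred_N)
    joint_true = combine_separate(y_C, y_N)
    wrong = joint_pred != joint_true
    return EvaluationReport(
        mode="separate",
        n_test=test.n_obs,
        misclassification_rate=float(wrong.mean()),
        rate_C=float(np.mean(pred_C != y_C)),
        rate_N=float(np.mean(pred_N != y_N)),
        confusion_C=_confusion(y_C, pred_C, clf_C.classes),
        confusion_N=_confusion(y_N, pred_N, clf_N.classes),
        n_mispredictions=int(wrong.sum()),
    )


def random_guess_rate(n_classes: int) -> float:
    """Expected misclassification of uniform guessing over ``n_classes``."""
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    return 1.0 - 1.0 / n_classes


@dataclass
class PredictiveReactionSet:
    """Reactions with nonzero LASSO coefficients, per class and pooled."""

    per_class: dict
    union: frozenset

    @property
    def n_unique(self) -> int:
        return len(self.union)


def predictive_reactions(classifier: TrainedClassifier) -> PredictiveReactionSet:
    """Extract the predictive fluxes at the selected penalty."""
    nz = classifier.estimator.nonzero_features()
    feats = classifier.feature_ids
    per_class = {c: sorted(feats[j] for j in idx) for c, idx in nz.items()}
    union = frozenset(r for rs in per_class.values() for r in rs)
    return PredictiveReactionSet(per_class=per_class, union=union)


def combine_predictive_sets(
    set_C: PredictiveReactionSet, set_N: PredictiveReactionSet
) -> dict:
    """Union/intersection summary across the carbon and nitrogen models."""
    u, i = set_C.union | set_N.union, set_C.union & set_N.union
    return {
        "n_C": len(set_C.union),
        "n_N": len(set_N.union),
        "n_shared": len(i),
        "n_unique": len(u),
        "union": sorted(u),
        "intersection": sorted(i),
    }


def ablation_study(
    train_ds: FluxDataset,
    test_ds: FluxDataset,
    reaction_ids,
    config: ClassifierConfig,
) -> pd.DataFrame:
    """Drop one reaction at a time, retrain both separate models, re-score.

    Retraining reuses the same seed and penalty-selection procedure so the
    reported delta reflects the feature removal only. Returns a table with the
    combined misclassification per dropped reaction and its delta vs. the
    no-drop baseline (stored in ``df.attrs["baseline"]``).
    """
    missing = [r for r in reaction_ids if r not in set(train_ds.X.columns)]
    if missing:
        raise ValueError(f"unknown reactions: {missing}")

    def fit_and_score(drop: str | None) -> float:
        keep = [c for c in train_ds.X.columns if c != drop]
        pair = []
        for mode in ("separate_C", "separate_N"):
            cfg = replace(config, mode=mode)
            X, y = build_features(train_ds, cfg, restrict_to=keep)
            pair.append(train(X, y, cfg))
        # restrict test features to the surviving columns before scoring
        test_restricted = FluxDataset(
            X=test_ds.X[keep],
            carbon_labels=test_ds.carbon_labels,
            nitrogen_labels=test_ds.nitrogen_labels,
            biomass=test_ds.biomass,
            replicate_id=test_ds.replicate_id,
            impurity_record=test_ds.impurity_record,
        )
        return score(test_restricted, tuple(pair), config).misclassification_rate

    baseline = fit_and_score(None)
    rows = [
        {"reaction": rid, "misclassification_rate": (r := fit_and_score(rid)),
         "delta": r - baseline}
        for rid in reaction_ids
    ]
    out = pd.DataFrame(rows)
    out.attrs["baseline"] = baseline
    return out


def novel_substrate_protocol(
    clf_C: TrainedClassifier,
    clf_N: TrainedClassifier,
    novel: FluxDataset,
    config: ClassifierConfig,
    novel_axis: str = "C",
) -> dict:
    """How an unseen substrate is mapped onto the known classes.

    ``novel`` must be simulated with a substrate (on ``novel_axis``) absent
    from the classifiers' training labels. Returns the frequency table of
    predicted known classes on the novel axis and the accuracy on the seen
    axis.
    """
    if novel_axis not in ("C", "N"):
        raise ValueError("novel_axis must be 'C' or 'N'")
    X_C, y_C = build_features(novel, replace(config, mode="separate_C"))
    X_N, y_N = build_features(novel, replace(config, mode="separate_N"))
    pred_C = predict(clf_C, X_C[clf_C.feature_ids])
    pred_N = predict(clf_N, X_N[clf_N.feature_ids])
    if novel_axis == "C":
        novel_pred, seen_pred, seen_true = pred_C, pred_N, y_N
    else:
        novel_pred, seen_pred, seen_true = pred_N, pred_C, y_C
    values, counts = np.unique(novel_pred, return_counts=True)
    freq = {str(v): c / len(novel_pred) for v, c in zip(values, counts)}
    return {
        "novel_axis": novel_axis,
        "n_obs": novel.n_obs,
        "predicted_frequencies": dict(sorted(freq.items(), key=lambda kv: -kv[1])),
        "seen_axis_accuracy": float(np.mean(seen_pred == seen_true)),
    }


def select_distinct_substrates(
    flux_profiles: pd.DataFrame, k: int, seed: int = 0
) -> list[str]:
    """Pick ``k`` substrates with maximally distinct flux signatures.

    ``flux_profiles`` has one impurity-free profile per candidate substrate
    (rows = substrates). Profiles are k-means clustered and the member closest
    to each centroid is returned, in stable row order.
    """
    if k > len(flux_profiles):
        raise ValueError(f"k={k} exceeds the {len(flux_profiles)} candidate profiles")
    X = flux_profiles.to_numpy(dtype=float)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
    chosen = []
    for c in range(k):
        members = np.flatnonzero(km.labels_ == c)
        d = np.linalg.norm(X[members] - km.cluster_centers_[c], axis=1)
        chosen.append(members[int(np.argmin(d))])
    return [flux_profiles.index[i] for i in sorted(chosen)]
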