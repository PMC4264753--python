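import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import fluxinfer as fi
from fluxinfer.classify import L1MultinomialLogisticCV

from conftest import FAST


def separable_two_class(n=60, n_noise=4, seed=0):
    """Feature f0 is +1 for class A, -1 for class B; the rest pure noise."""
    rng = np.random.default_rng(seed)
    y = np.array(["A", "B"] * (n // 2))
    f = np.where(y == "A", 1.0, -1.0) + rng.normal(scale=0.05, size=n)
    X = np.column_stack([f] + [rng.normal(size=n) for _ in range(n_noise)])
    cols = ["f0"] + [f"noise{i}" for i in range(n_noise)]
    return pd.DataFrame(X, columns=cols), y


class TestBuildFeatures:
    def test_small_fluxes_zeroed(self, ds77):
        cfg = fi.ClassifierConfig()
        doctored = ds77.subset(np.arange(5))
        doctored.X.iloc[0, 0] = 5e-7
        X, _ = fi.build_features(doctored, cfg)
        assert X.iloc[0, 0] == 0.0
        assert (X.abs().to_numpy() >= 1e-6).sum() + (X.to_numpy() == 0).sum() == X.size

    def test_joint_mode_yields_49_labels(self, ds77):
        _, labels = fi.build_features(ds77, fi.ClassifierConfig(mode="joint"))
        assert len(np.unique(labels)) == 49

    def test_separate_modes_yield_axis_labels(self, ds77):
        _, y_C = fi.build_features(ds77, fi.ClassifierConfig(mode="separate_C"))
        _, y_N = fi.build_features(ds77, fi.ClassifierConfig(mode="separate_N"))
        assert set(y_C) == set(ds77.carbon_labels)
        assert set(y_N) == set(ds77.nitrogen_labels)

    def test_restrict_to_filters_columns(self, ds77):
        keep = list(ds77.X.columns[:5])
        X, _ = fi.build_features(ds77, fi.ClassifierConfig(), restrict_to=set(keep))
        assert list(X.columns) == keep

    def test_disjoint_restriction_errors(self, ds77):
        with pytest.raises(ValueError, match="restrict_to"):
            fi.build_features(ds77, fi.ClassifierConfig(), restrict_to={"nope"})


class TestTrain:
    def test_separable_single_feature_recovered(self):
        X, y = separable_two_class()
        cfg = fi.ClassifierConfig(mode="separate_C", **FAST)
        clf = fi.train(X, y, cfg)
        assert clf.cv_misclassification.min() == 0.0
        support = {r["reaction"] for _, r in clf.coefficient_table().iterrows()}
        assert support == {"f0"}
        assert (fi.predict(clf, X) == y).all()

    def test_full_shrinkage_limit_predicts_majority_class(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        y = np.array(["maj"] * 35 + ["min"] * 15)
        cfg = fi.ClassifierConfig(lambda_path=[1e6, 1e5], **{k: v for k, v in FAST.items()
                                                             if k == "seed"})
        clf = fi.train(X, y, cfg)
        est = clf.estimator
        # at the selected (huge) penalty every feature coefficient is zero
        assert np.all(est.coef_ == 0)
        assert (est.predict(X) == "maj").all()

    def test_permuted_labels_reach_the_chance_rate(self):
        """Null check: with labels shuffled, CV misclassification sits at 1 - 1/k."""
        rng = np.random.default_rng(0)
        k, n = 3, 90
        X = pd.DataFrame(rng.normal(size=(n, 5)))
        y0 = np.repeat([f"c{i}" for i in range(k)], n // k)
        rates = []
        for _ in range(30):
            y = rng.permutation(y0)
            est = L1MultinomialLogisticCV(lambda_path=[1.0, 0.5], n_folds=3,
                                          random_state=17)
            est.fit(X, y)
            rates.append(est.cv_misclassification_.min())
        mean = np.mean(rates)
        se = np.std(rates, ddof=1) / np.sqrt(len(rates))
        null = 1 - 1 / k
        assert abs(mean - null) < 3 * se + 0.02

    def test_missing_class_is_named_in_error(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 3)))
        y = np.array(["a"] * 9 + ["b"])
        with pytest.raises(ValueError, match="'b'"):
            fi.train(X, y, fi.ClassifierConfig(n_folds=3))

    def test_single_class_errors(self):
        X = pd.DataFrame(np.zeros((6, 2)))
        with pytest.raises(ValueError, match="2 classes"):
            fi.train(X, np.array(["a"] * 6), fi.ClassifierConfig())

    def test_sparsity_nonincreasing_in_penalty(self):
        X, y = separable_two_class(n=80, n_noise=8, seed=3)
        path = [1.0, 0.3, 0.1, 0.03, 0.01]
        nnz = []
        for lam in path:
            est = L1MultinomialLogisticCV(lambda_path=[lam], n_folds=2, random_state=0)
            est.fit(X, y)
            nnz.append(int((est.coef_ != 0).sum()))
        assert all(a <= b for a, b in zip(nnz, nnz[1:])), nnz

    def test_leave_one_out_matches_brute_force(self):
        """CV at n_folds = n equals an independent held-out loop at the same path."""
        from sklearn.linear_model import LogisticRegression

        X, y = separable_two_class(n=14, n_noise=2, seed=5)
        path = [0.5, 0.05]
        est = L1MultinomialLogisticCV(lambda_path=path, n_folds=len(y), random_state=0)
        est.fit(X, y)

        Xs = (X.to_numpy() - est.means_) / est.scales_
        brute = np.zeros(len(path))
        for i in range(len(y)):
            tr = np.delete(np.arange(len(y)), i)
            for li, lam in enumerate(path):
                m = LogisticRegression(l1_ratio=1.0, solver="saga",
                                       C=1.0 / (len(tr) * lam), tol=1e-3,
                                       max_iter=1000, random_state=0)
                m.fit(Xs[tr], y[tr])
                brute[li] += float(m.predict(Xs[[i]])[0] != y[i])
        brute /= len(y)
        np.testing.assert_allclose(est.cv_misclassification_, brute, atol=1e-12)


class TestPredict:
    def test_training_labels_recovered_on_separable_toy(self):
        X, y = separable_two_class(seed=2)
        clf = fi.train(X, y, fi.ClassifierConfig(**FAST))
        assert (fi.predict(clf, X) == y).all()

    def test_all_zero_vector_goes_to_largest_intercept_class(self, sep_classifiers):
        clf_C, _ = sep_classifiers
        est = clf_C.estimator
        zero = pd.DataFrame(np.zeros((1, len(clf_C.feature_ids))),
                            columns=clf_C.feature_ids)
        scores = est.decision_function(zero)
        # a zero flux vector standardizes to -means/scales; the argmax of the
        # resulting affine score must be the predicted class
        assert fi.predict(clf_C, zero)[0] == est.classes_[np.argmax(scores)]

    def test_intercept_shift_invariance(self, sep_classifiers):
        clf_C, _ = sep_classifiers
        est = clf_C.estimator
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(20, len(clf_C.feature_ids))),
                         columns=clf_C.feature_ids)
        before = est.predict(X)
        est.intercept_ = est.intercept_ + 7.3  # softmax scores shift-invariant
        after = est.predict(X)
        est.intercept_ = est.intercept_ - 7.3
        np.testing.assert_array_equal(before, after)

    def test_column_mismatch_errors(self, sep_classifiers):
        clf_C, _ = sep_classifiers
        X = pd.DataFrame(np.zeros((2, 3)), columns=["x", "y", "z"])
        with pytest.raises(ValueError, match="feature columns"):
            fi.predict(clf_C, X)


class TestCombineSeparate:
    def test_all_correct_pairs_give_zero_misclassification(self):
        pred = fi.combine_separate(["a", "b"], ["x", "y"])
        np.testing.assert_array_equal(pred, ["a|x", "b|y"])

    def test_disjoint_error_sets_add(self):
        true_C = np.array(["a"] * 10)
        true_N = np.array(["x"] * 10)
        pred_C, pred_N = true_C.copy(), true_N.copy()
        pred_C[:3] = "b"   # 3 carbon errors
        pred_N[5:7] = "y"  # 2 nitrogen errors, disjoint observations
        joint = fi.combine_separate(pred_C, pred_N)
        truth = fi.combine_separate(true_C, true_N)
        assert (joint != truth).sum() == 5

    def test_overlapping_errors_counted_once_per_observation(self):
        joint = fi.combine_separate(["b"], ["y"])
        truth = fi.combine_separate(["a"], ["x"])
        assert (joint != truth).sum() == 1

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            fi.combine_separate(["a"], ["x", "y"])


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, sep_classifiers, split77):
        _, test_ds = split77
        clf_C, _ = sep_classifiers
        X, _ = fi.build_features(test_ds, fi.ClassifierConfig(mode="separate_C"))
        back = fi.TrainedClassifier.from_json(clf_C.to_json())
        np.testing.assert_array_equal(
            fi.predict(clf_C, X[clf_C.feature_ids]),
            fi.predict(back, X[back.feature_ids]),
        )
        assert back.lambda_selected == clf_C.lambda_selected


class TestGlmnetCrossCheck:
    def test_agrees_with_r_glmnet_on_separable_toy(self, tmp_path):
        """Independent oracle: R's glmnet on the same data reaches the same
        perfect test accuracy and a comparably sparse support."""
        X, y = separable_two_class(n=80, n_noise=4, seed=11)
        Xte, yte = separable_two_class(n=40, n_noise=4, seed=12)
        clf = fi.train(X, y, fi.ClassifierConfig(**FAST))
        ours = float(np.mean(fi.predict(clf, Xte) == yte))

        train_csv, test_csv = tmp_path / "tr.csv", tmp_path / "te.csv"
        X.assign(label=y).to_csv(train_csv, index=False)
        Xte.assign(label=yte).to_csv(test_csv, index=False)
        rscript = textwrap.dedent(f"""
            suppressMessages(library(glmnet))
            tr <- read.csv("{train_csv}"); te <- read.csv("{test_csv}")
            x <- as.matrix(tr[, 1:5]); y <- tr$label
            set.seed(1)
            fit <- cv.glmnet(x, y, family="multinomial", alpha=1, nfolds=3,
                             type.measure="class")
            pred <- predict(fit, as.matrix(te[, 1:5]), s="lambda.min", type="class")
            cat(mean(pred == te$label), "\\n")
            co <- coef(fit, s="lambda.min")
            cat(sum(sapply(co, function(m) sum(m[-1, ] != 0))), "\\n")
        """)
        out = subprocess.run(["Rscript", "-e", rscript], capture_output=True, text=True)
        assert out.returncode == 0, out.stderr
        glmnet_acc, glmnet_nnz = out.stdout.split()
        assert ours == 1.0 and float(glmnet_acc) == 1.0
        our_nnz = int((clf.estimator.coef_ != 0).sum())
        assert our_nnz <= 3 and int(glmnet_nnz) <= 6
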