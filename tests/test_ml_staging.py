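"""SMOTE, BP network, classifier panel, cross-validation, feature sets."""

import numpy as np
import pytest

from serumftir import (
    SMOTEConfig,
    bp_train,
    classifier_panel,
    compare_feature_sets,
    cross_validate,
    generate_cohort,
    make_classifier,
    smote,
)
from serumftir.ml_staging import BPClassifier, MVLRClassifier, feature_matrix_for, staging_cohort
from tests.conftest import small_cohort_config


class TestSMOTE:
    def test_all_classes_balanced_to_majority(self, rng):
        X = rng.normal(size=(50, 3))
        y = np.r_[np.zeros(10), np.ones(40)]
        Xb, yb = smote(X, y, SMOTEConfig(k_neighbors=5, seed=1))
        assert (yb == 0).sum() == (yb == 1).sum() == 40

    def test_synthetic_points_lie_on_minority_segments(self, rng):
        X = rng.normal(size=(25, 2))
        y = np.r_[np.zeros(5), np.ones(20)]
        Xb, yb = smote(X, y, SMOTEConfig(k_neighbors=3, seed=2))
        minority = X[:5]
        for s in Xb[25:]:
            on_segment = False
            for i in range(5):
                for j in range(5):
                    if i == j:
                        continue
                    v = minority[j] - minority[i]
                    t = np.dot(s - minority[i], v) / np.dot(v, v)
                    resid = np.linalg.norm(s - (minority[i] + t * v))
                    if -1e-9 <= t <= 1 + 1e-9 and resid < 1e-9:
                        on_segment = True
            assert on_segment

    def test_k_clamped_with_warning_for_tiny_class(self, rng):
        X = rng.normal(size=(23, 2))
        y = np.r_[np.zeros(3), np.ones(20)]
        with pytest.warns(UserWarning, match="clamping"):
            Xb, yb = smote(X, y, SMOTEConfig(k_neighbors=5, seed=3))
        assert (yb == 0).sum() == 20

    def test_singleton_class_error_names_the_class(self, rng):
        X = rng.normal(size=(21, 2))
        y = np.array(["rare"] + ["common"] * 20)
        with pytest.raises(ValueError, match="rare"):
            smote(X, y, SMOTEConfig(seed=0))


class TestBP:
    def test_learns_xor(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float) * 2 - 1
        y = np.array([0, 1, 1, 0])
        clf = bp_train(X, y, hidden_units=8, epochs=5000, learning_rate=0.5, seed=0)
        assert np.array_equal(clf.predict(X), y)

    def test_zero_epochs_reproducible_from_seed(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.integers(0, 3, 30)
        a = BPClassifier(epochs=0, seed=9).fit(X, y).predict(X)
        b = BPClassifier(epochs=0, seed=9).fit(X, y).predict(X)
        np.testing.assert_array_equal(a, b)

    def test_separable_blobs_generalize(self):
        rng = np.random.default_rng(1)
        Xtr = np.vstack([rng.normal(0, 0.5, (40, 2)), rng.normal(3, 0.5, (40, 2))])
        ytr = np.r_[np.zeros(40), np.ones(40)]
        Xte = np.vstack([rng.normal(0, 0.5, (40, 2)), rng.normal(3, 0.5, (40, 2))])
        clf = bp_train(Xtr, ytr, epochs=1000, seed=2)
        assert np.mean(clf.predict(Xte) == ytr) >= 0.95

    def test_loss_nonincreasing_for_small_learning_rate(self, rng):
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 2, 40)
        clf = BPClassifier(epochs=200, learning_rate=0.001, seed=0).fit(X, y)
        diffs = np.diff(clf.loss_curve_)
        assert (diffs <= 1e-10).all()

    def test_nonfinite_loss_aborts_with_diagnostics(self, rng):
        X = rng.normal(size=(20, 3))
        X[3, 1] = np.nan  # corrupt input must abort, not fit silently
        y = rng.integers(0, 2, 20)
        with pytest.raises(RuntimeError, match="non-finite"):
            BPClassifier(epochs=500, seed=0).fit(X, y)


class TestPanel:
    def test_registry_lists_exactly_eight_methods(self):
        assert len(classifier_panel()) == 8
        assert set(classifier_panel()) == {
            "BP", "KNN", "RF", "DT", "Logistic", "SVM", "MVLR", "PLS-DA",
        }

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            make_classifier("gradient-boost")

    def test_mvlr_equals_full_rank_plsda(self, rng):
        X = rng.normal(size=(60, 4))
        y = rng.integers(0, 3, 60)
        from serumftir import PLSDA

        mvlr = MVLRClassifier().fit(X, y)
        pls = PLSDA(n_components=4, scale=False).fit(X, y)
        np.testing.assert_array_equal(mvlr.predict(X), pls.predict(X))

    def test_every_method_survives_smoke_cohort(self, rng):
        X = rng.normal(size=(45, 5))
        X[:15] += 2
        X[15:30] -= 2
        y = np.repeat([0, 1, 2], 15)
        for name in classifier_panel():
            clf = make_classifier(name, seed=0)
            clf.fit(X, y)
            assert len(clf.predict(X)) == 45


class TestCrossValidate:
    def test_constant_classifier_scores_majority_share(self, rng):
        class Majority:
            def fit(self, X, y):
                vals, counts = np.unique(y, return_counts=True)
                self.c = vals[np.argmax(counts)]
                return self

            def predict(self, X):
                return np.full(len(X), self.c)

        X = rng.normal(size=(60, 2))
        y = np.r_[np.zeros(45), np.ones(15)]
        rep = cross_validate(
            X, y, method=lambda seed=0, **kw: Majority(), folds=5, repeats=1,
            seed=0, smote_inside=False,
        )
        assert rep.accuracy == pytest.approx(0.75, abs=1e-9)

    def test_same_seed_gives_identical_report(self, rng):
        X = rng.normal(size=(60, 3))
        y = rng.integers(0, 2, 60)
        a = cross_validate(X, y, method="KNN", folds=5, repeats=2, seed=7)
        b = cross_validate(X, y, method="KNN", folds=5, repeats=2, seed=7)
        assert a.accuracy == b.accuracy
        assert a.confusion.equals(b.confusion)

    def test_confusion_counts_cover_all_held_out_predictions(self, rng):
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 2, 40)
        rep = cross_validate(X, y, method="DT", folds=4, repeats=3, seed=1)
        assert rep.confusion.to_numpy().sum() == 40 * 3

    def test_folds_reduced_for_tiny_class_with_warning(self, rng):
        X = rng.normal(size=(24, 2))
        y = np.r_[np.zeros(20), np.ones(4)]
        with pytest.warns(UserWarning, match="reducing folds"):
            rep = cross_validate(X, y, method="KNN", folds=10, repeats=1, seed=0)
        assert rep.folds == 4

    def test_leakage_mode_inflates_null_accuracy(self):
        """SMOTE before splitting leaks synthetic near-copies into test folds."""
        rng = np.random.default_rng(123)
        accs = {True: [], False: []}
        for s in range(5):
            X = rng.normal(size=(60, 5))
            y = np.r_[np.zeros(45), np.ones(15)]
            for leak in (True, False):
                rep = cross_validate(
                    X, y, method="KNN", folds=5, repeats=1, seed=s,
                    smote_inside=True, leak_preprocessing=leak,
                    method_kwargs={"n_neighbors": 1},
                )
                accs[leak].append(rep.accuracy)
        assert np.mean(accs[True]) > np.mean(accs[False]) + 0.05

    def test_label_permutation_yields_chance_accuracy(self, rng):
        """Every panel method stays at chance on permuted labels."""
        X = rng.normal(size=(60, 3))
        y = np.repeat([0, 1, 2], 20)
        for name in classifier_panel():
            kw = {"epochs": 150} if name == "BP" else {}
            accs = []
            for perm in range(20):
                yp = np.random.default_rng(perm).permutation(y)
                rep = cross_validate(
                    X, yp, method=name, folds=3, repeats=1, seed=perm,
                    method_kwargs=kw,
                )
                accs.append(rep.accuracy)
            # binomial 95% band around chance for the mean of 20 permutations
            assert abs(np.mean(accs) - 1 / 3) < 0.08, name


class TestFeatureSets:
    def test_comparison_table_shape_and_confusions(self):
        cohort = generate_cohort(small_cohort_config(seed=4, n_per_group=8))
        table, reports = compare_feature_sets(
            cohort, group=None, methods=["KNN", "PLS-DA"],
            feature_sets=("1D-sd", "combined"), folds=3, repeats=1, seed=0,
        )
        assert table.shape == (2, 2)
        rep = reports[("KNN", "1D-sd")]
        assert rep.confusion.to_numpy().sum() == len(cohort)

    def test_table3_layout_eight_methods_three_feature_sets(self):
        cohort = generate_cohort(small_cohort_config(seed=5, n_per_group=6))
        table, _ = compare_feature_sets(
            cohort, group=None, methods=list(classifier_panel()),
            feature_sets=("1D-raw", "1D-sd", "combined"), folds=2, repeats=1,
            seed=0, method_kwargs=None,
        )
        assert table.shape == (8, 3)

    def test_staging_task_uses_group_plus_controls(self):
        cohort = generate_cohort(small_cohort_config(seed=6, n_per_group=9))
        sub = staging_cohort(cohort, "GC")
        groups = {s.meta["group"] for s in sub.spectra}
        assert groups == {"GC", "Control"}
        stages = {s.meta["stage"] for s in sub.spectra}
        assert stages == {1, 2, 3, 4}

    def test_zero_effect_cohort_is_at_chance(self):
        """With all stage effects off, staging cannot beat chance."""
        cfg = small_cohort_config(
            seed=7, n_per_group=9,
            stage_scales={1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0},
        )
        cohort = generate_cohort(cfg)
        sub = staging_cohort(cohort, "LC")
        fm = feature_matrix_for(sub, "2D-sd")
        rep = cross_validate(
            fm.values, fm.labels["stage"].to_numpy(), method="KNN",
            folds=3, repeats=2, seed=0,
        )
        assert rep.accuracy < 0.5  # 4 classes, chance ~= 0.28

    def test_accuracy_monotone_in_effect_scale_spacing(self):
        """Staging accuracy grows as stage effect scales spread apart."""
        means = []
        for m in (0.2, 0.6, 1.0):
            accs = []
            for seed in (0, 1, 2):
                cfg = small_cohort_config(
                    seed=seed, n_per_group=9, noise=0.01,
                    stage_scales={1: 0.5 * m, 2: 1.0 * m, 3: 0.3 * m, 4: 0.0},
                )
                sub = staging_cohort(generate_cohort(cfg), "CC")
                fm = feature_matrix_for(sub, "2D-sd")
                rep = cross_validate(
                    fm.values, fm.labels["stage"].to_numpy(), method="KNN",
                    folds=3, repeats=1, seed=seed,
                )
                accs.append(rep.accuracy)
            means.append(np.mean(accs))
        assert means[0] <= means[1] + 0.02
        assert means[1] <= means[2] + 0.02
        assert means[2] > means[0]
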