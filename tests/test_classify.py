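"""Classification metrics, AUC, SVM wrapper, baselines and fold safety."""

from dataclasses import replace

import numpy as np
import pytest

from somroi import (
    CvConfig,
    EffectRegion,
    PhantomConfig,
    SomConfig,
    VolumeStack,
    cross_validate,
    extract_features,
    generate_cohort,
    metrics_from_confusion,
    pca_baseline,
    roc_auc,
    svm_rbf_fit,
    vaf_baseline,
)
from somroi.classify import block_average
from somroi.pipeline import fit_tissue_model, project_subjects
from somroi.som3d import PhaseSchedule


def brute_force_auc(scores, labels):
    """All-pairs Mann-Whitney count, ties worth 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestMetrics:
    def test_confusion_arithmetic(self):
        m = metrics_from_confusion(tp=9, fp=2, tn=8, fn=1)
        assert m["sensitivity"] == pytest.approx(0.9)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["accuracy"] == pytest.approx(0.85)

    def test_auc_perfect_and_brute_force(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = rng.integers(4, 30)
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # force ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels) == brute_force_auc(scores, labels)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(12)
        scores = rng.standard_normal(40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        base = roc_auc(scores, labels)
        assert roc_auc(np.exp(scores), labels) == base
        assert roc_auc(3 * scores + 7, labels) == base

    def test_auc_undefined_for_single_class(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestSvm:
    def test_separable_toy_is_learned(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-2, 0.1, (10, 2)), rng.normal(2, 0.1, (10, 2))])
        y = np.array([0] * 10 + [1] * 10)
        clf = svm_rbf_fit(X, y, seed=0)
        assert (clf.predict(X) == y).all()

    def test_permuted_labels_score_near_chance(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(-2, 0.1, (20, 2)), rng.normal(2, 0.1, (20, 2))])
        y = rng.permutation([0] * 20 + [1] * 20)
        clf = svm_rbf_fit(X, y, seed=1)
        assert clf.best_score_ < 0.75

    def test_duplicated_columns_give_identical_predictions(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 4))
        y = (X[:, 0] > 0).astype(int)
        Xq = rng.standard_normal((10, 4))
        a = svm_rbf_fit(X, y, seed=3).predict(Xq)
        b = svm_rbf_fit(np.hstack([X, X]), y, seed=3).predict(np.hstack([Xq, Xq]))
        np.testing.assert_array_equal(a, b)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            svm_rbf_fit(np.zeros((4, 2)), np.zeros(4))


class TestBaselines:
    def test_pca_line_needs_one_component(self):
        t = np.linspace(0, 1, 10)
        X = np.column_stack([t, 2 * t, -t])
        z, _, proj = pca_baseline(X, variance=0.95)
        assert proj.named_steps["pca"].n_components_ == 1

    def test_pca_all_components_preserve_distances_and_trace(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((20, 6))
        z, _, proj = pca_baseline(X, variance=1.0)
        from scipy.spatial.distance import pdist

        zs = proj.named_steps["scaler"].transform(X)
        np.testing.assert_allclose(pdist(zs @ proj.named_steps["pca"].components_.T),
                                   pdist(z), atol=1e-9)
        ev = proj.named_steps["pca"].explained_variance_
        total = np.var(zs, axis=0, ddof=1).sum()
        assert np.isclose(ev.sum(), total, rtol=1e-9)

    def test_vaf_feature_count_and_constants(self):
        rng = np.random.default_rng(4)
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask.ravel()[:100] = True
        vols = rng.random((3, 6, 6, 6))
        assert vaf_baseline(vols, mask).shape == (3, 100)
        const = vaf_baseline(np.full((2, 6, 6, 6), 0.5), mask)
        assert (const == 0.5).all()
        ones = block_average(np.ones((6, 6, 6)), 4)
        np.testing.assert_array_equal(ones, np.ones((2, 2, 2)))


@pytest.fixture(scope="module")
def tiny_models():
    cfg = PhantomConfig(
        grid_shape=(12, 12, 12), n_per_class=4,
        effect_regions=(), baseline_smoothness=2.0, noise_sd=0.02, seed=9,
    )
    gm, wm = generate_cohort(cfg)
    som = SomConfig(
        lattice_shape=(3, 3, 1),
        phase1=PhaseSchedule(0.1, None, 2, 1.0),
        phase2=PhaseSchedule(0.01, None, 3, 0.5),
        subsample=256, seed=5,
    )
    return gm, wm, fit_tissue_model(gm, som), fit_tissue_model(wm, replace(som, seed=6))


class TestFeatureExtraction:
    def test_zero_volume_gives_zero_features(self, tiny_models):
        gm, wm, mg, mw = tiny_models
        zero_gm = VolumeStack(np.zeros_like(gm.volumes[:1]), gm.labels[:1], "GM")
        zero_wm = VolumeStack(np.zeros_like(wm.volumes[:1]), wm.labels[:1], "WM")
        feats = extract_features(zero_gm, zero_wm, mg, mw)
        np.testing.assert_array_equal(feats, np.zeros_like(feats))

    def test_homogeneity_degree_one(self, tiny_models):
        gm, wm, mg, mw = tiny_models
        f1 = project_subjects(mg, gm.volumes[0])
        f2 = project_subjects(mg, 2.0 * gm.volumes[0])
        np.testing.assert_allclose(f2, 2.0 * f1, rtol=1e-12)

    def test_class_mean_subject_gets_mean_projection(self, tiny_models):
        gm, _, mg, _ = tiny_models
        mean0 = gm.volumes[gm.labels == 0].mean(axis=0)
        f_mean = project_subjects(mg, mean0)[0]
        f_each = project_subjects(mg, gm.volumes[gm.labels == 0])
        np.testing.assert_allclose(f_mean, f_each.mean(axis=0), atol=1e-12)

    def test_grid_mismatch_raises(self, tiny_models):
        _, _, mg, _ = tiny_models
        with pytest.raises(ValueError):
            project_subjects(mg, np.zeros((5, 5, 5)))


class TestCrossValidate:
    def test_too_few_subjects_per_class_raises(self, small_cohort):
        gm, wm = small_cohort  # 5 per class
        with pytest.raises(ValueError, match="use k <="):
            cross_validate(gm, wm, CvConfig(n_folds=10, seed=0))

    def test_small_cohort_report_structure(self, small_cohort):
        gm, wm = small_cohort
        som = SomConfig(
            lattice_shape=(3, 3, 1),
            phase1=PhaseSchedule(0.1, None, 2, 1.0),
            phase2=PhaseSchedule(0.01, None, 3, 0.5),
            subsample=256,
        )
        report = cross_validate(gm, wm, CvConfig(n_folds=3, seed=2, som=som))
        assert report.n_folds == 3
        assert len(report.folds) == 3
        for f in report.folds:
            assert f.tp + f.fp + f.tn + f.fn == f.n_test
        for lo, hi in (report.accuracy, report.sensitivity, report.specificity):
            assert 0.0 <= lo <= 1.0
        assert 0.0 <= report.auc <= 1.0
        # ROC points are monotone nondecreasing in both coordinates
        assert (np.diff(report.roc_points[:, 0]) >= 0).all()
        assert (np.diff(report.roc_points[:, 1]) >= 0).all()
        # every subject is scored exactly once across folds
        all_idx = np.concatenate([f.test_index for f in report.folds])
        assert sorted(all_idx.tolist()) == list(range(gm.n_subjects))

    def test_roi_features_not_worse_than_vaf_on_strong_effect(self):
        """Qualitative ordering at fixed seeds: ROI features match or beat
        voxels-as-features when a compact lesion is planted (regression
        property, not a theorem)."""
        cfg = PhantomConfig(
            grid_shape=(16, 16, 16), n_per_class=8,
            effect_regions=(EffectRegion((8.0, 8.0, 8.0), 3.0, 0.3),),
            baseline_smoothness=3.0, noise_sd=0.05, seed=21,
        )
        gm, wm = generate_cohort(cfg)
        som = SomConfig(lattice_shape=(3, 3, 2),
                        phase1=PhaseSchedule(0.1, None, 3, 1.0),
                        phase2=PhaseSchedule(0.01, None, 5, 0.5), subsample=512)
        roi_rep = cross_validate(gm, wm, CvConfig(n_folds=4, seed=21, som=som))
        vaf_rep = cross_validate(gm, wm, CvConfig(n_folds=4, seed=21, method="vaf"))
        assert roi_rep.accuracy[0] >= vaf_rep.accuracy[0]

    def test_vaf_and_pca_methods_run(self, small_cohort):
        gm, wm = small_cohort
        for method in ("vaf", "pca"):
            report = cross_validate(
                gm, wm,
                CvConfig(n_folds=2, seed=3, method=method, vaf_downsample=2),
            )
            assert report.method == method
            assert 0.0 <= report.accuracy[0] <= 1.0
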