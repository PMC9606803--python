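"""Feature extraction, LOOCV linear SVM, AUC and FDR-corrected correlations."""

import numpy as np
import pandas as pd
import pytest

from assomap.biomarker_eval import (
    FeatureMatrix,
    confusion_metrics,
    extract_cluster_features,
    loocv_linear_svm,
    pearson_with_fdr,
    roc_auc,
)
from assomap.data_io import VoxelMap


def _maps_for(values_list, mask):
    return [VoxelMap(values=v, affine=np.eye(4), kind="asso_z", mask=mask)
            for v in values_list]


class TestFeatureExtraction:
    def test_constant_map_gives_constant_feature(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        cmask = np.zeros((4, 4, 4), dtype=bool)
        cmask[1:3, 1:3, 1:3] = True
        maps = _maps_for([np.full((4, 4, 4), 2.5)], mask)
        fm = extract_cluster_features({"asso_z": maps}, {"c1": cmask},
                                      ["s1"], ["AD"])
        assert fm.X[0, 0] == 2.5

    def test_single_voxel_mask(self, rng):
        mask = np.ones((4, 4, 4), dtype=bool)
        cmask = np.zeros((4, 4, 4), dtype=bool)
        cmask[2, 1, 3] = True
        v = rng.standard_normal((4, 4, 4))
        fm = extract_cluster_features({"m": _maps_for([v], mask)},
                                      {"c": cmask}, ["s1"], ["HC"])
        assert fm.X[0, 0] == v[2, 1, 3]

    def test_matches_explicit_mean(self, rng):
        mask = np.ones((5, 5, 5), dtype=bool)
        cmask = rng.random((5, 5, 5)) > 0.6
        vals = [rng.standard_normal((5, 5, 5)) for _ in range(3)]
        fm = extract_cluster_features({"m": _maps_for(vals, mask)},
                                      {"c": cmask},
                                      ["a", "b", "c"], ["AD", "AD", "HC"])
        for i, v in enumerate(vals):
            expected = np.mean([v[idx] for idx in zip(*np.where(cmask))])
            assert fm.X[i, 0] == pytest.approx(expected)

    def test_mask_outside_map_mask_rejected(self, rng):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0:2] = True
        cmask = np.zeros((4, 4, 4), dtype=bool)
        cmask[3, 3, 3] = True
        v = np.where(mask, 1.0, 0.0)
        with pytest.raises(ValueError, match="outside"):
            extract_cluster_features({"m": _maps_for([v], mask)}, {"c": cmask},
                                     ["s"], ["AD"])


class TestConfusionMetrics:
    def test_all_correct(self):
        labels = ["AD"] * 3 + ["HC"] * 4
        assert confusion_metrics(labels, labels) == (100.0, 100.0, 100.0)

    def test_always_predicting_control(self):
        labels = np.array(["AD"] * 5 + ["HC"] * 5)
        preds = np.array(["HC"] * 10)
        acc, sens, spec = confusion_metrics(preds, labels)
        assert sens == 0.0 and spec == 100.0 and acc == 50.0

    def test_study_confusion_matrix(self):
        # TP=31 FN=5 TN=38 FP=4 with 36 patients / 42 controls
        labels = np.array(["AD"] * 36 + ["HC"] * 42)
        preds = np.array(["AD"] * 31 + ["HC"] * 5 + ["HC"] * 38 + ["AD"] * 4)
        acc, sens, spec = confusion_metrics(preds, labels)
        assert round(acc, 2) == 88.46
        assert round(sens, 2) == 86.11
        assert round(spec, 2) == 90.48


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([3, 4, 1, 2], ["AD", "AD", "HC", "HC"]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([1, 1, 1, 1], ["AD", "AD", "HC", "HC"]) == 0.5

    def test_pair_enumeration_example(self):
        # AD={3,2}, HC={1,2}: pairs (3>1)=1, (3>2)=1, (2>1)=1, (2=2)=0.5
        # -> 3.5 / 4 = 0.875
        assert roc_auc([3, 2, 1, 2], ["AD", "AD", "HC", "HC"]) == 0.875

    def test_matches_sklearn_trapezoid(self, rng):
        for _ in range(10):
            scores = rng.standard_normal(30)
            labels = np.where(rng.random(30) < 0.5, "AD", "HC")
            if len(set(labels)) < 2:
                continue
            from sklearn.metrics import roc_auc_score

            ref = roc_auc_score((labels == "AD").astype(int), scores)
            assert roc_auc(scores, labels) == pytest.approx(ref, abs=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], ["AD", "AD"])


class TestLoocvSvm:
    def _features(self, X, groups):
        return FeatureMatrix(X=np.asarray(X, float),
                             feature_names=[f"f{i}" for i in range(np.asarray(X).shape[1])],
                             subject_ids=[f"s{i}" for i in range(len(groups))],
                             groups=np.asarray(groups))

    def test_wide_margin_separable_is_perfect(self, rng):
        n = 20
        x_ad = rng.normal(5.0, 0.3, (n, 2))
        x_hc = rng.normal(-5.0, 0.3, (n, 2))
        X = np.vstack([x_ad, x_hc])
        # verify separability margin before asserting
        assert x_ad[:, 0].min() - x_hc[:, 0].max() > 2.0
        fm = self._features(X, ["AD"] * n + ["HC"] * n)
        report = loocv_linear_svm(fm, seed=0)
        assert report.accuracy == 100.0
        assert report.auc == 1.0

    def test_chance_level_on_random_features(self, rng):
        accs = []
        for _ in range(20):
            X = rng.standard_normal((40, 3))
            fm = self._features(X, ["AD"] * 20 + ["HC"] * 20)
            accs.append(loocv_linear_svm(fm, seed=0).accuracy)
        mean_acc = np.mean(accs)
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        # LOOCV on null features is slightly pessimistic; the mean should sit
        # near 50% and certainly within a few SE of it
        assert abs(mean_acc - 50.0) <= max(2 * se, 10.0)

    def test_deterministic(self, rng):
        X = rng.standard_normal((16, 2))
        fm = self._features(X, ["AD"] * 8 + ["HC"] * 8)
        r1 = loocv_linear_svm(fm, seed=5)
        r2 = loocv_linear_svm(fm, seed=5)
        np.testing.assert_array_equal(r1.decisions, r2.decisions)
        assert (r1.predictions == r2.predictions).all()

    def test_subject_permutation_permutes_outputs(self, rng):
        X = rng.standard_normal((14, 2))
        groups = np.array(["AD"] * 7 + ["HC"] * 7)
        fm = self._features(X, groups)
        r1 = loocv_linear_svm(fm, seed=0)
        perm = rng.permutation(14)
        fm_p = self._features(X[perm], groups[perm])
        r2 = loocv_linear_svm(fm_p, seed=0)
        np.testing.assert_allclose(r2.decisions, r1.decisions[perm], atol=1e-10)

    def test_report_internal_consistency(self, rng):
        X = rng.standard_normal((20, 2))
        X[:10] += 1.0
        fm = self._features(X, ["AD"] * 10 + ["HC"] * 10)
        r = loocv_linear_svm(fm, seed=0)
        c = r.confusion
        assert c["tp"] + c["fn"] == 10 and c["tn"] + c["fp"] == 10
        assert r.accuracy == pytest.approx(100.0 * (c["tp"] + c["tn"]) / 20)
        assert r.sensitivity == pytest.approx(100.0 * c["tp"] / 10)
        assert r.specificity == pytest.approx(100.0 * c["tn"] / 10)

    def test_tiny_class_rejected(self, rng):
        fm = self._features(rng.standard_normal((3, 2)), ["AD", "HC", "HC"])
        with pytest.raises(ValueError):
            loocv_linear_svm(fm)


class TestPearsonFdr:
    def _fm(self, X, groups=None):
        X = np.asarray(X, float)
        n = X.shape[0]
        return FeatureMatrix(X=X, feature_names=[f"f{i}" for i in range(X.shape[1])],
                             subject_ids=[f"s{i}" for i in range(n)],
                             groups=np.asarray(groups or ["AD"] * n))

    def test_perfect_correlation(self):
        x = np.arange(10, dtype=float)
        scores = pd.DataFrame({"mmse": x, "moca": x[::-1]})
        out = pearson_with_fdr(self._fm(x[:, None]), scores)
        r_mmse = out[(out.feature == "f0") & (out.score == "mmse")].r.iloc[0]
        r_moca = out[(out.feature == "f0") & (out.score == "moca")].r.iloc[0]
        assert r_mmse == pytest.approx(1.0)
        assert r_moca == pytest.approx(-1.0)

    def test_bh_step_up_uniform_grid(self):
        # p = (0.01..0.05), family of 5 -> every q = 0.05
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        _, q, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, 0.05)
        # and the step-up formula oracle min_{j>=i} m p_(j) / j
        m = len(p)
        q_ref = np.minimum.accumulate((m * p / np.arange(1, m + 1))[::-1])[::-1]
        np.testing.assert_allclose(q, q_ref)

    def test_single_test_q_equals_p(self, rng):
        x = rng.standard_normal(12)
        scores = pd.DataFrame({"mmse": rng.standard_normal(12)})
        out = pearson_with_fdr(self._fm(x[:, None]), scores,
                               score_names=("mmse",))
        assert out.q.iloc[0] == pytest.approx(out.p.iloc[0])

    def test_q_monotone_in_p(self, rng):
        X = rng.standard_normal((30, 4))
        scores = pd.DataFrame({"mmse": rng.standard_normal(30),
                               "moca": rng.standard_normal(30)})
        out = pearson_with_fdr(self._fm(X), scores).sort_values("p")
        assert (np.diff(out.q.to_numpy()) >= -1e-12).all()

    def test_zero_variance_flagged_not_fatal(self, rng):
        X = np.column_stack([np.ones(10), rng.standard_normal(10)])
        scores = pd.DataFrame({"mmse": rng.standard_normal(10)})
        with pytest.warns(UserWarning, match="zero variance"):
            out = pearson_with_fdr(self._fm(X), scores, score_names=("mmse",))
        assert np.isnan(out.r.iloc[0])
        assert np.isfinite(out.r.iloc[1])


class TestNestedLoocv:
    def test_nested_evaluation_on_planted_cohort(self):
        """Fold-wise cluster definition still separates the groups when the
        planted effect is strong, and never lets the held-out subject into
        feature definition."""
        from assomap.asso_core import subject_asso_pipeline
        from assomap.experiments import nested_loocv_svm
        from assomap.pipeline import RunConfig, _preprocess_branches
        from assomap.synthetic_cohort import CohortConfig, simulate_cohort

        cfg = CohortConfig(n_ad=8, n_hc=8, seed=77)
        cohort = simulate_cohort(cfg)
        asso_branch, fc_branch = _preprocess_branches(
            cohort, RunConfig(cohort=cfg), with_fc=True
        )
        mask = cohort.masks.brain
        asso_maps = [subject_asso_pipeline(b, mask)["asso_z_s"]
                     for b in asso_branch]
        report = nested_loocv_svm(asso_maps, fc_branch, cohort.phenotypes,
                                  mask, svm_seed=0)
        assert len(report.predictions) == 16
        assert report.accuracy >= 75.0
        assert report.auc >= 0.8
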