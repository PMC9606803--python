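"""Monte-Carlo experiments over synthetic cohorts.

These drive the validation study: type-I error of the corrected group
inference on null cohorts, recovery of the planted hub-Asso deficit and
hub-DMN FC increase, classifier performance, and brain-behaviour correlation
directions.  Both the test suite and the acceptance script run these.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import biomarker_eval, fc_seed, group_inference
from .asso_core import subject_asso_pipeline, threshold_adjacency
from .biomarker_eval import ClassifierReport, FeatureMatrix
from .pipeline import RunConfig, _preprocess_branches
from .synthetic_cohort import CohortConfig, simulate_cohort, simulate_null_cohort

DEFAULT_N_PERM = 200


@dataclass
class NullCohortResult:
    seed: int
    n_significant: int


@dataclass
class PlantedCohortResult:
    seed: int
    asso_recovered: bool  # significant AD<HC cluster overlapping the hub
    fc_recovered: bool  # significant AD>HC FC cluster overlapping a DMN region
    hub_t_mean: float
    classifier: ClassifierReport
    correlations: pd.DataFrame  # feature x score r/p/q table


def analyze_null_cohort(
    seed: int,
    cfg: CohortConfig | None = None,
    n_perm: int = DEFAULT_N_PERM,
) -> NullCohortResult:
    """Full Asso-branch analysis of one null cohort; counts corrected hits."""
    ccfg = cfg if cfg is not None else CohortConfig(seed=seed)
    cohort = simulate_null_cohort(ccfg)
    rcfg = RunConfig(cohort=ccfg)
    asso_branch, _ = _preprocess_branches(cohort, rcfg, with_fc=False)
    maps = [
        subject_asso_pipeline(clean, cohort.masks.brain)["asso_z_s"]
        for clean in asso_branch
    ]
    design = group_inference.build_design(cohort.phenotypes)
    _, clusters = group_inference.permutation_cluster_correction(
        maps, design, n_perm=n_perm, seed=seed
    )
    return NullCohortResult(seed=seed, n_significant=len(clusters.significant()))


def analyze_planted_cohort(
    seed: int,
    cfg: CohortConfig | None = None,
    n_perm: int = DEFAULT_N_PERM,
) -> PlantedCohortResult:
    """Both analysis branches on one planted cohort.

    The FC seed is the recovered AD<HC Asso cluster when one is found
    (mirroring the seed definition of the main analysis); otherwise the true
    hub mask is used so the feature-level read-outs stay defined (the
    recovery flag is already False in that case).
    """
    ccfg = cfg if cfg is not None else CohortConfig(seed=seed)
    cohort = simulate_cohort(ccfg)
    rcfg = RunConfig(cohort=ccfg)
    hub = cohort.region_mask(ccfg.hub_region)
    dmn_union = np.zeros_like(hub)
    for r in ccfg.dmn_regions:
        dmn_union |= cohort.region_mask(r)
    mask = cohort.masks.brain

    asso_branch, fc_branch = _preprocess_branches(cohort, rcfg, with_fc=True)
    asso_maps = [
        subject_asso_pipeline(clean, mask)["asso_z_s"] for clean in asso_branch
    ]
    design = group_inference.build_design(cohort.phenotypes)
    asso_stat, asso_clusters = group_inference.permutation_cluster_correction(
        asso_maps, design, n_perm=n_perm, seed=seed
    )
    neg_hits = [
        c for c in asso_clusters.significant()
        if c.tail == "neg" and np.any(c.mask & hub)
    ]
    asso_recovered = bool(neg_hits)

    if neg_hits:
        seed_mask = neg_hits[0].mask & mask
    else:
        seed_mask = hub
    seed_def = fc_seed.SeedDefinition(mask=seed_mask, label="hub_seed")
    fc_maps = [
        fc_seed.compute_seed_fc_map(clean, seed_def, mask) for clean in fc_branch
    ]
    _, fc_clusters = group_inference.permutation_cluster_correction(
        fc_maps, design, n_perm=n_perm, seed=seed + 1
    )
    fc_recovered = any(
        c.tail == "pos" and np.any(c.mask & dmn_union)
        for c in fc_clusters.significant()
    )

    # feature-level read-outs from the true region masks
    subject_ids = [p.subject_id for p in cohort.phenotypes]
    groups = [p.group for p in cohort.phenotypes]
    fm_asso = biomarker_eval.extract_cluster_features(
        {"asso_z": asso_maps}, {"hub": hub}, subject_ids, groups
    )
    fc_masks = {
        f"dmn{r}": cohort.region_mask(r) for r in ccfg.dmn_regions
    }
    fm_fc = biomarker_eval.extract_cluster_features(
        {"fc_z": fc_maps}, fc_masks, subject_ids, groups
    )
    features = FeatureMatrix(
        X=np.hstack([fm_asso.X, fm_fc.X]),
        feature_names=fm_asso.feature_names + fm_fc.feature_names,
        subject_ids=subject_ids,
        groups=np.asarray(groups),
    )
    report = biomarker_eval.loocv_linear_svm(features, seed=seed)
    scores = biomarker_eval.phenotype_scores(cohort.phenotypes)
    correlations = biomarker_eval.pearson_with_fdr(features, scores)

    return PlantedCohortResult(
        seed=seed,
        asso_recovered=asso_recovered,
        fc_recovered=fc_recovered,
        hub_t_mean=float(asso_stat.values[hub].mean()),
        classifier=report,
        correlations=correlations,
    )


def correlation_sign_table(results: list[PlantedCohortResult]) -> pd.DataFrame:
    """Per (feature, score) pair: fraction of cohorts recovering the planted
    sign (positive for the hub Asso feature, negative for the FC features)."""
    rows = []
    corr0 = results[0].correlations
    for _, row in corr0.iterrows():
        feat, score = row["feature"], row["score"]
        expected = 1.0 if feat.startswith("asso") else -1.0
        ok = []
        for r in results:
            sel = r.correlations[
                (r.correlations.feature == feat) & (r.correlations.score == score)
            ]
            ok.append(np.sign(sel.r.iloc[0]) == expected)
        rows.append({"feature": feat, "score": score,
                     "expected_sign": expected,
                     "recovery_rate": float(np.mean(ok))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Asso brute-force agreement
# ---------------------------------------------------------------------------


def brute_force_asso_counts(adj: np.ndarray):
    """Explicit neighbour-pair counting (the independent oracle)."""
    v = adj.shape[0]
    n = np.zeros(v, dtype=np.int64)
    k = np.zeros(v, dtype=np.int64)
    for i in range(v):
        nbrs = np.flatnonzero(adj[i])
        n[i] = len(nbrs)
        edges = 0
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                if adj[nbrs[a], nbrs[b]]:
                    edges += 1
        k[i] = edges
    return n, k, n * (n - 1) // 2 - k


def random_correlated_instance(
    rng: np.random.Generator, max_voxels: int = 200, t: int = 100
) -> np.ndarray:
    """A random multivoxel series with latent-group structure (V x T)."""
    v = int(rng.integers(30, max_voxels + 1))
    n_latent = int(rng.integers(2, 6))
    latent = rng.standard_normal((n_latent, t))
    loadings = (rng.random((v, n_latent)) < 0.15) * rng.uniform(0.5, 1.2, (v, n_latent))
    return loadings @ latent + rng.standard_normal((v, t))


def asso_oracle_agreement(
    n_instances: int = 50, seed: int = 0, max_voxels: int = 200, t: int = 100
) -> tuple[int, int]:
    """Count instances where the fast Asso computation matches the oracle
    exactly (integer equality at every voxel)."""
    from .asso_core import asso_counts_from_adjacency

    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        series = random_correlated_instance(rng, max_voxels=max_voxels, t=t)
        adj = threshold_adjacency(series)
        fast = asso_counts_from_adjacency(adj)
        n_ref, k_ref, asso_ref = brute_force_asso_counts(adj)
        if (
            np.array_equal(fast.n_neighbors, n_ref)
            and np.array_equal(fast.k_edges, k_ref)
            and np.array_equal(fast.asso.astype(np.int64), asso_ref)
        ):
            agree += 1
    return agree, n_instances


# ---------------------------------------------------------------------------
# nested (non-circular) leave-one-out evaluation
# ---------------------------------------------------------------------------


def nested_loocv_svm(
    asso_maps,
    fc_bolds,
    phenotypes,
    mask: np.ndarray,
    voxel_p: float = 0.001,
    svm_seed: int = 0,
) -> ClassifierReport:
    """Leave-one-out evaluation with cluster definition inside each fold.

    The default evaluation extracts features from clusters found on the full
    sample and then cross-validates — a circular design.  Here the
    discriminative clusters (the AD<HC Asso cluster, then the AD>HC seed-FC
    cluster) are re-estimated from the 39 training subjects of every fold, so
    the held-out subject never influences feature definition.  Folds whose
    training data yield no suprathreshold Asso cluster fall back to the
    global Asso-z mean as the single feature.
    """
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    n = len(phenotypes)
    groups = np.asarray([p.group for p in phenotypes])
    decisions = np.empty(n)
    predictions = np.empty(n, dtype=object)
    for held in range(n):
        train = [i for i in range(n) if i != held]
        design_tr = group_inference.build_design([phenotypes[i] for i in train])
        stat = group_inference.voxelwise_glm_ttest(
            [asso_maps[i] for i in train], design_tr, mask=mask
        )
        table = group_inference.cluster_extract(stat, voxel_p=voxel_p)
        negs = [c for c in table.clusters if c.tail == "neg"]
        feat_cols = []
        if negs:
            seed_mask = negs[0].mask & mask
            feat_cols.append(
                np.array([m.values[seed_mask].mean() for m in asso_maps])
            )
            seed_def = fc_seed.SeedDefinition(mask=seed_mask, label="fold_seed")
            fc_maps = [
                fc_seed.compute_seed_fc_map(b, seed_def, mask) for b in fc_bolds
            ]
            fc_stat = group_inference.voxelwise_glm_ttest(
                [fc_maps[i] for i in train], design_tr, mask=mask
            )
            fc_table = group_inference.cluster_extract(fc_stat, voxel_p=voxel_p)
            pos = [
                c for c in fc_table.clusters
                if c.tail == "pos" and not (c.mask & seed_mask).any()
            ]
            if pos:
                cmask = pos[0].mask & mask
                feat_cols.append(
                    np.array([m.values[cmask].mean() for m in fc_maps])
                )
        else:
            feat_cols.append(np.array([m.values[mask].mean() for m in asso_maps]))
        X = np.column_stack(feat_cols)
        scaler = StandardScaler().fit(X[train])
        clf = SVC(kernel="linear", C=1.0, random_state=svm_seed)
        clf.fit(scaler.transform(X[train]), groups[train])
        xt = scaler.transform(X[held : held + 1])
        d = float(clf.decision_function(xt)[0])
        if clf.classes_[1] != "AD":
            d = -d
        decisions[held] = d
        predictions[held] = str(clf.predict(xt)[0])
    acc, sens, spec = biomarker_eval.confusion_metrics(predictions, groups)
    auc = biomarker_eval.roc_auc(decisions, groups)
    pos_lab = groups == "AD"
    confusion = {
        "tp": int(np.sum(pos_lab & (predictions == "AD"))),
        "fn": int(np.sum(pos_lab & (predictions != "AD"))),
        "tn": int(np.sum(~pos_lab & (predictions != "AD"))),
        "fp": int(np.sum(~pos_lab & (predictions == "AD"))),
    }
    return ClassifierReport(
        accuracy=acc, sensitivity=sens, specificity=spec, auc=auc,
        confusion=confusion, decisions=decisions, predictions=predictions,
    )


# ---------------------------------------------------------------------------
# classifier sanity experiments
# ---------------------------------------------------------------------------


def separable_svm_accuracy(seed: int = 0, n_per_group: int = 20) -> float:
    """LOOCV accuracy on margin-verified separable features (percent)."""
    rng = np.random.default_rng(seed)
    x_ad = rng.normal(4.0, 0.4, (n_per_group, 2))
    x_hc = rng.normal(-4.0, 0.4, (n_per_group, 2))
    margin = x_ad.min(axis=0)[0] - x_hc.max(axis=0)[0]
    if margin <= 1.0:
        raise RuntimeError("separability margin not realized")
    fm = FeatureMatrix(
        X=np.vstack([x_ad, x_hc]),
        feature_names=["f0", "f1"],
        subject_ids=[f"s{i}" for i in range(2 * n_per_group)],
        groups=np.asarray(["AD"] * n_per_group + ["HC"] * n_per_group),
    )
    return biomarker_eval.loocv_linear_svm(fm, seed=seed).accuracy


def chance_svm_accuracies(
    n_reps: int = 20, seed: int = 0, n_per_group: int = 20
) -> np.ndarray:
    """LOOCV accuracies on class-independent random features (percent)."""
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(n_reps):
        fm = FeatureMatrix(
            X=rng.standard_normal((2 * n_per_group, 3)),
            feature_names=["f0", "f1", "f2"],
            subject_ids=[f"s{i}" for i in range(2 * n_per_group)],
            groups=np.asarray(["AD"] * n_per_group + ["HC"] * n_per_group),
        )
        accs.append(biomarker_eval.loocv_linear_svm(fm, seed=seed).accuracy)
    return np.asarray(accs)
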