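"""Biomarker evaluation: cluster features, LOOCV linear SVM, brain-behaviour
correlations with Benjamini-Hochberg FDR.

Features are cluster-mean map values (Asso-z within the hub cluster, seed
FC-z within each coupled cluster).  Classification is leave-one-out: for each
held-out subject the features are standardized on the training fold only, a
linear SVM (C=1) is fitted, and accuracy / sensitivity / specificity / AUC
are computed from the pooled held-out predictions and decision values, with
the patient group as the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .data_io import PhenotypeRecord, VoxelMap

POSITIVE_CLASS = "AD"


@dataclass
class FeatureMatrix:
    X: np.ndarray
    feature_names: list[str]
    subject_ids: list[str]
    groups: np.ndarray  # array of "AD"/"HC"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.groups = np.asarray(self.groups)
        if self.X.shape != (len(self.subject_ids), len(self.feature_names)):
            raise ValueError("feature matrix shape mismatch")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains missing values")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "group", self.groups)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        feats = [c for c in df.columns if c not in ("subject_id", "group")]
        return cls(
            X=df[feats].to_numpy(float),
            feature_names=feats,
            subject_ids=[str(s) for s in df["subject_id"]],
            groups=df["group"].to_numpy(),
        )


@dataclass
class ClassifierReport:
    accuracy: float  # percent
    sensitivity: float  # percent
    specificity: float  # percent
    auc: float
    confusion: dict[str, int]  # tp / fn / tn / fp
    decisions: np.ndarray
    predictions: np.ndarray

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "confusion": self.confusion,
            "decisions": [float(x) for x in self.decisions],
            "predictions": [str(x) for x in self.predictions],
        }


def extract_cluster_features(
    maps_by_label: dict[str, Sequence[VoxelMap]],
    cluster_masks: dict[str, np.ndarray],
    subject_ids: Sequence[str],
    groups: Sequence[str],
) -> FeatureMatrix:
    """Cluster-mean features.

    ``maps_by_label`` maps a map family (e.g. ``asso_z``, ``fcz_L_INS``) to the
    per-subject maps; ``cluster_masks`` maps a cluster label to its boolean
    mask.  One feature per (family, cluster) pair where the label encodes
    which mask applies to which family (same-name pairing: each family is
    averaged within each mask given for it).
    """
    n = len(subject_ids)
    features = []
    names = []
    for fam, maps in maps_by_label.items():
        if len(maps) != n:
            raise ValueError(f"family {fam!r} has {len(maps)} maps for {n} subjects")
        for lab, mask in cluster_masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != maps[0].values.shape:
                raise ValueError(f"cluster mask {lab!r} not on the map grid")
            if not mask.any():
                raise ValueError(f"cluster mask {lab!r} is empty")
            if np.any(mask & ~maps[0].mask):
                raise ValueError(f"cluster mask {lab!r} extends outside the map mask")
            col = np.array([m.values[mask].mean() for m in maps])
            features.append(col)
            names.append(f"{fam}:{lab}")
    return FeatureMatrix(
        X=np.column_stack(features),
        feature_names=names,
        subject_ids=list(subject_ids),
        groups=np.asarray(list(groups)),
    )


def confusion_metrics(
    predictions: Sequence[str], labels: Sequence[str]
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) as percentages; AD is positive."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.size == 0:
        raise ValueError("empty predictions")
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels differ in length")
    pos = labels == POSITIVE_CLASS
    neg = ~pos
    tp = int(np.sum(pos & (predictions == POSITIVE_CLASS)))
    tn = int(np.sum(neg & (predictions != POSITIVE_CLASS)))
    acc = 100.0 * (tp + tn) / labels.size
    sens = 100.0 * tp / pos.sum() if pos.any() else np.nan
    spec = 100.0 * tn / neg.sum() if neg.any() else np.nan
    return acc, sens, spec


def roc_auc(decision_values: Sequence[float], labels: Sequence[str]) -> float:
    """AUC via the Mann-Whitney formulation: P(score_AD > score_HC) + P(tie)/2."""
    d = np.asarray(decision_values, dtype=np.float64)
    labels = np.asarray(labels)
    pos = d[labels == POSITIVE_CLASS]
    neg = d[labels != POSITIVE_CLASS]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present for AUC")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (pos.size * neg.size))


def loocv_linear_svm(features: FeatureMatrix, seed: int = 0) -> ClassifierReport:
    """Leave-one-out linear SVM (C=1) with within-fold standardization."""
    X, y = features.X, features.groups
    n = len(y)
    for g in np.unique(y):
        if np.sum(y == g) < 2:
            raise ValueError(f"need >= 2 subjects in group {g!r}")
    decisions = np.empty(n)
    predictions = np.empty(n, dtype=object)
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        if len(np.unique(y[train])) < 2:
            raise ValueError("single-class training fold")
        scaler = StandardScaler().fit(X[train])
        clf = SVC(kernel="linear", C=1.0, random_state=seed)
        clf.fit(scaler.transform(X[train]), y[train])
        xt = scaler.transform(X[i : i + 1])
        d = float(clf.decision_function(xt)[0])
        # orient the decision value so larger means more AD-like
        if clf.classes_[1] != POSITIVE_CLASS:
            d = -d
        decisions[i] = d
        predictions[i] = str(clf.predict(xt)[0])
    acc, sens, spec = confusion_metrics(predictions, y)
    auc = roc_auc(decisions, y)
    pos = y == POSITIVE_CLASS
    confusion = {
        "tp": int(np.sum(pos & (predictions == POSITIVE_CLASS))),
        "fn": int(np.sum(pos & (predictions != POSITIVE_CLASS))),
        "tn": int(np.sum(~pos & (predictions != POSITIVE_CLASS))),
        "fp": int(np.sum(~pos & (predictions == POSITIVE_CLASS))),
    }
    return ClassifierReport(
        accuracy=acc, sensitivity=sens, specificity=spec, auc=auc,
        confusion=confusion, decisions=decisions, predictions=predictions,
    )


def pearson_with_fdr(
    features: FeatureMatrix,
    scores: pd.DataFrame,
    score_names: Sequence[str] = ("mmse", "moca"),
) -> pd.DataFrame:
    """Pearson r / p per (feature, score) pair; BH step-up q over the family.

    ``scores`` is indexed like the feature rows (one row per subject) with the
    score columns.  Zero-variance vectors are flagged and excluded from the
    BH family with a warning.
    """
    import warnings

    rows = []
    for feat_idx, feat in enumerate(features.feature_names):
        x = features.X[:, feat_idx]
        for sc in score_names:
            y = scores[sc].to_numpy(float)
            if len(y) != len(x):
                raise ValueError("scores and features differ in length")
            if len(x) < 4:
                raise ValueError("need >= 4 paired observations")
            if x.std() == 0 or y.std() == 0:
                warnings.warn(
                    f"zero variance in pair ({feat}, {sc}); excluded",
                    stacklevel=2,
                )
                rows.append({"feature": feat, "score": sc, "r": np.nan,
                             "p": np.nan, "q": np.nan})
                continue
            r, p = sp_stats.pearsonr(x, y)
            rows.append({"feature": feat, "score": sc, "r": float(r),
                         "p": float(p), "q": np.nan})
    df = pd.DataFrame(rows)
    tested = df["p"].notna()
    if tested.any():
        _, q, _, _ = multipletests(df.loc[tested, "p"], method="fdr_bh")
        df.loc[tested, "q"] = q
    return df


def phenotype_scores(phenotypes: Sequence[PhenotypeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in phenotypes],
            "mmse": [p.mmse for p in phenotypes],
            "moca": [p.moca for p in phenotypes],
        }
    )
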