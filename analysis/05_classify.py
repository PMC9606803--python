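"""Biomarker evaluation: cluster-mean features into a LOOCV linear SVM.

Features are the mean Asso-z within the seed (deficit) cluster and the mean
FC-z within each AD>HC coupling cluster.  Reports accuracy, sensitivity,
specificity and AUC from the pooled held-out predictions
(results/classifier_report.json, results/features.tsv).
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _paths import COHORT_DIR, MAPS_DIR, RESULTS

from assomap.biomarker_eval import extract_cluster_features, loocv_linear_svm
from assomap.data_io import load_mask, load_phenotypes, load_voxel_map


def main() -> None:
    mask, _ = load_mask(COHORT_DIR / "mask_brain.nii.gz")
    phenos = load_phenotypes(COHORT_DIR / "phenotypes.tsv")
    subject_ids = [p.subject_id for p in phenos]
    groups = [p.group for p in phenos]

    asso_maps = [
        load_voxel_map(MAPS_DIR / f"{s}_asso_z_s.nii.gz", "asso_z", mask)
        for s in subject_ids
    ]
    fc_maps = [
        load_voxel_map(MAPS_DIR / f"{s}_fcz.nii.gz", "fc_z", mask)
        for s in subject_ids
    ]
    seed_mask, _ = load_mask(MAPS_DIR / "seed_mask.nii.gz")
    fm = extract_cluster_features(
        {"asso_z": asso_maps}, {"seed": seed_mask & mask}, subject_ids, groups
    )
    import numpy as np

    from assomap.biomarker_eval import FeatureMatrix

    for cpath in sorted(MAPS_DIR.glob("fc_cluster*.nii.gz")):
        cmask, _ = load_mask(cpath)
        fc_fm = extract_cluster_features(
            {"fc_z": fc_maps}, {cpath.stem.split(".")[0]: cmask & mask},
            subject_ids, groups
        )
        fm = FeatureMatrix(
            X=np.hstack([fm.X, fc_fm.X]),
            feature_names=fm.feature_names + fc_fm.feature_names,
            subject_ids=subject_ids,
            groups=fm.groups,
        )

    fm.to_frame().to_csv(RESULTS / "features.tsv", sep="\t", index=False)
    report = loocv_linear_svm(fm, seed=7)
    with open(RESULTS / "classifier_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)

    print(f"features: {fm.feature_names}")
    print(f"accuracy    {report.accuracy:.2f}%")
    print(f"sensitivity {report.sensitivity:.2f}%")
    print(f"specificity {report.specificity:.2f}%")
    print(f"AUC         {report.auc:.3f}")
    print(f"confusion   {report.confusion}")

    # honest (non-circular) estimate: clusters re-defined inside every fold
    from _paths import CLEAN_FC_DIR

    from assomap.data_io import load_bold_dataset
    from assomap.experiments import nested_loocv_svm

    fc_bolds = [
        load_bold_dataset(CLEAN_FC_DIR / f"{s}_clean.nii.gz", subject_id=s)[0]
        for s in subject_ids
    ]
    nested = nested_loocv_svm(asso_maps, fc_bolds, phenos, mask, svm_seed=7)
    with open(RESULTS / "classifier_report_nested.json", "w") as fh:
        json.dump(nested.to_dict(), fh, indent=2)
    print("\nnested (fold-wise cluster definition):")
    print(f"accuracy    {nested.accuracy:.2f}%   AUC {nested.auc:.3f}")


if __name__ == "__main__":
    main()
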