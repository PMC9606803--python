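"""Seed-based functional connectivity of the recovered Asso-deficit region.

The seed is the AD<HC cluster from the association analysis; Fisher-z FC
maps are computed per subject on the smoothed-branch data and compared
between groups with the same covariate-adjusted permutation procedure.
Writes results/fc_clusters.tsv and the significant FC cluster masks.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _paths import CLEAN_FC_DIR, COHORT_DIR, MAPS_DIR, RESULTS

from assomap.data_io import (
    load_bold_dataset,
    load_mask,
    load_phenotypes,
    save_mask,
    save_voxel_map,
)
from assomap.fc_seed import SeedDefinition, compute_seed_fc_map
from assomap.group_inference import build_design, permutation_cluster_correction


def main() -> None:
    mask, affine = load_mask(COHORT_DIR / "mask_brain.nii.gz")
    seed_mask, _ = load_mask(MAPS_DIR / "seed_mask.nii.gz")
    seed = SeedDefinition(mask=seed_mask & mask, label="asso_deficit",
                          provenance="asso AD<HC cluster")
    phenos = load_phenotypes(COHORT_DIR / "phenotypes.tsv")

    maps = []
    for p in phenos:
        bold, _ = load_bold_dataset(
            CLEAN_FC_DIR / f"{p.subject_id}_clean.nii.gz", subject_id=p.subject_id
        )
        vm = compute_seed_fc_map(bold, seed, mask)
        save_voxel_map(vm, MAPS_DIR / f"{p.subject_id}_fcz.nii.gz")
        maps.append(vm)

    design = build_design(phenos)
    stat, clusters = permutation_cluster_correction(
        maps, design, n_perm=1000, seed=8
    )
    table = clusters.to_frame()
    table.to_csv(RESULTS / "fc_clusters.tsv", sep="\t", index=False)

    print(f"seed: {int(seed.mask.sum())} voxels; df={stat.df}")
    print(table.round(3).to_string(index=False))
    n_saved = 0
    for c in clusters.significant():
        if c.tail == "pos" and not (c.mask & seed.mask).any():
            n_saved += 1
            save_mask(c.mask, affine, MAPS_DIR / f"fc_cluster{n_saved}.nii.gz")
    print(f"\n{n_saved} AD>HC coupling clusters saved for feature extraction")


if __name__ == "__main__":
    main()
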