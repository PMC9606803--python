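"""End-to-end orchestration: simulate -> preprocess (two branches) -> Asso
branch group stats -> seed FC branch -> classification -> correlations.

Two preprocessing branches are materialized from a shared volume-dropped
input: the Asso branch is NOT smoothed before the graph computation (the
Asso map itself is z-scored and smoothed afterwards), while the FC branch
smooths the BOLD volumes first and then detrends / filters / regresses.

Every stage writes a JSON manifest (parameters, input hashes) so a rerun
with the same config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import asso_core, biomarker_eval, fc_seed, group_inference, preprocess
from .data_io import (
    BoldDataset,
    MotionParams,
    TissueMasks,
    VoxelMap,
    phenotypes_to_frame,
)
from .synthetic_cohort import CohortConfig, SyntheticCohort, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run.

    Every stochastic stage carries an explicit seed; loading a config with a
    missing seed fails validation before any computation starts.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_drop: int = 10
    band: tuple[float, float] = (0.01, 0.1)
    fd_threshold: float = 0.5
    scrub_window: tuple[int, int] = (2, 1)
    filter_method: str = "butter"
    global_signal: bool = True
    scrub_before_filter: bool = False
    r_threshold: float = 0.25
    use_absolute: bool = False
    fwhm_mm: float = 6.0
    voxel_p: float = 0.001
    cluster_p: float = 0.05
    n_perm: int = 1000
    connectivity: int = 18
    perm_seed: int | None = 7
    svm_seed: int | None = 7
    seed_from: str = "cluster"  # or "sphere"
    seed_sphere_radius_mm: float = 6.0

    def validate(self) -> None:
        if self.perm_seed is None or self.svm_seed is None:
            raise ValueError("every stochastic stage needs an explicit seed "
                             "(perm_seed / svm_seed)")
        if self.cohort.seed is None:
            raise ValueError("cohort seed is missing")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        d["scrub_window"] = list(self.scrub_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            cd = dict(d["cohort"])
            for key in ("grid", "dmn_regions"):
                if key in cd and isinstance(cd[key], list):
                    cd[key] = tuple(cd[key])
            d["cohort"] = CohortConfig(**cd)
        for key in ("band", "scrub_window"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _digest(obj) -> str:
    if isinstance(obj, np.ndarray):
        return hashlib.sha256(np.ascontiguousarray(obj).tobytes()).hexdigest()[:16]
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write_manifest(outdir: Path, stage: str, params: dict, outputs: dict) -> None:
    manifest = {
        "stage": stage,
        "params": params,
        "outputs": {k: _digest(v) for k, v in outputs.items()},
        "wall_time_s": outputs.get("_wall", None),
    }
    manifest["outputs"].pop("_wall", None)
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


@dataclass
class RunResult:
    """In-memory results of one full run."""

    cohort: SyntheticCohort
    asso_z_maps: list[VoxelMap]
    fcs_maps: list[VoxelMap]
    asso_stat: group_inference.StatMap
    asso_clusters: group_inference.ClusterTable
    seed_def: fc_seed.SeedDefinition | None
    fc_maps: list[VoxelMap]
    fc_stat: group_inference.StatMap | None
    fc_clusters: group_inference.ClusterTable | None
    features: biomarker_eval.FeatureMatrix | None
    report: biomarker_eval.ClassifierReport | None
    correlations: "object"
    demographics: "object"


def _preprocess_branches(
    cohort: SyntheticCohort, cfg: RunConfig, with_fc: bool = True
) -> tuple[list[BoldDataset], list[BoldDataset]]:
    """Shared volume drop, then the Asso (unsmoothed) and FC (smoothed) branches."""
    asso_branch, fc_branch = [], []
    masks = cohort.masks
    for bold, motion, pheno in cohort.subjects:
        dropped, mot = preprocess.drop_initial_volumes(bold, motion, cfg.n_drop)
        fd = preprocess.compute_fd(mot)
        plan = preprocess.make_scrub_plan(
            fd, threshold=cfg.fd_threshold,
            n_before=cfg.scrub_window[0], n_after=cfg.scrub_window[1]
        )
        nuis = preprocess.build_nuisance_matrix(dropped, masks, mot)
        if not cfg.global_signal:
            keep = [i for i, l in enumerate(nuis.labels) if l != "global_mean"]
            nuis = preprocess.NuisanceMatrix(
                nuis.matrix[:, keep], [nuis.labels[i] for i in keep]
            )
        clean = preprocess.detrend_filter_regress(
            dropped, nuis, band=cfg.band, filter_method=cfg.filter_method
        )
        clean = preprocess.scrub_interpolate(clean, plan)
        asso_branch.append(clean)
        if not with_fc:
            continue

        # FC branch: smooth the volumes FIRST, then detrend/filter/regress
        sm_data = np.empty_like(dropped.data)
        for t in range(dropped.n_frames):
            vm = VoxelMap(values=dropped.data[..., t], affine=dropped.affine,
                          kind="t", mask=np.ones(dropped.shape3d, bool))
            sm_data[..., t] = asso_core.smooth_map(vm, cfg.fwhm_mm).values
        smoothed = dataclasses.replace(dropped, data=sm_data)
        nuis_fc = preprocess.build_nuisance_matrix(smoothed, masks, mot)
        clean_fc = preprocess.detrend_filter_regress(
            smoothed, nuis_fc, band=cfg.band, filter_method=cfg.filter_method
        )
        clean_fc = preprocess.scrub_interpolate(clean_fc, plan)
        fc_branch.append(clean_fc)
    return asso_branch, fc_branch


def run_all(cfg: RunConfig, outdir: str | Path | None = None) -> RunResult:
    """Execute every stage in dependency order; optionally write artifacts."""
    cfg.validate()
    t0 = time.time()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(out / "config.yaml")

    cohort = simulate_cohort(cfg.cohort)
    phenos = cohort.phenotypes
    mask = cohort.masks.brain

    asso_branch, fc_branch = _preprocess_branches(cohort, cfg)

    asso_z_maps, fcs_maps = [], []
    for clean in asso_branch:
        maps = asso_core.subject_asso_pipeline(
            clean, mask, r_threshold=cfg.r_threshold, fwhm_mm=cfg.fwhm_mm,
            use_absolute=cfg.use_absolute,
        )
        asso_z_maps.append(maps["asso_z_s"])
        fcs_maps.append(maps["fcs"])

    design = group_inference.build_design(phenos)
    asso_stat, asso_clusters = group_inference.permutation_cluster_correction(
        asso_z_maps, design, n_perm=cfg.n_perm, voxel_p=cfg.voxel_p,
        cluster_p=cfg.cluster_p, connectivity=cfg.connectivity,
        seed=cfg.perm_seed,
    )

    significant = asso_clusters.significant(cfg.cluster_p)
    seed_def = None
    fc_maps: list[VoxelMap] = []
    fc_stat = None
    fc_clusters = None
    if significant:
        # the seed is the area of reduced Asso in patients (negative tail);
        # fall back to the largest significant cluster of either sign
        negs = [c for c in significant if c.tail == "neg"]
        top = negs[0] if negs else significant[0]
        if cfg.seed_from == "sphere":
            seed_def = fc_seed.sphere_seed(
                np.array(top.peak_mm), cfg.seed_sphere_radius_mm,
                asso_stat.affine, mask.shape, label="seed"
            )
            seed_def.mask &= mask
        else:
            seed_def = fc_seed.SeedDefinition(
                mask=top.mask & mask, label="seed", provenance=f"cluster{top.cluster_id}"
            )
        fc_maps = [
            fc_seed.compute_seed_fc_map(clean, seed_def, mask)
            for clean in fc_branch
        ]
        fc_stat, fc_clusters = group_inference.permutation_cluster_correction(
            fc_maps, design, n_perm=cfg.n_perm, voxel_p=cfg.voxel_p,
            cluster_p=cfg.cluster_p, connectivity=cfg.connectivity,
            seed=cfg.perm_seed + 1,
        )

    features = None
    report = None
    correlations = None
    if seed_def is not None:
        cluster_masks = {"seed": seed_def.mask}
        maps_by = {"asso_z": asso_z_maps}
        if fc_clusters is not None:
            fc_sig = [c for c in fc_clusters.significant(cfg.cluster_p)
                      if not np.any(c.mask & seed_def.mask)]
            fam_masks = {}
            for i, c in enumerate(fc_sig, start=1):
                fam_masks[f"fc_cluster{i}"] = c.mask
            if fam_masks:
                features = biomarker_eval.extract_cluster_features(
                    {"asso_z": asso_z_maps}, {"seed": seed_def.mask},
                    [p.subject_id for p in phenos], [p.group for p in phenos],
                )
                fc_features = biomarker_eval.extract_cluster_features(
                    {"fc_z": fc_maps}, fam_masks,
                    [p.subject_id for p in phenos], [p.group for p in phenos],
                )
                features = biomarker_eval.FeatureMatrix(
                    X=np.hstack([features.X, fc_features.X]),
                    feature_names=features.feature_names + fc_features.feature_names,
                    subject_ids=features.subject_ids,
                    groups=features.groups,
                )
        if features is None:
            features = biomarker_eval.extract_cluster_features(
                {"asso_z": asso_z_maps}, {"seed": seed_def.mask},
                [p.subject_id for p in phenos], [p.group for p in phenos],
            )
        report = biomarker_eval.loocv_linear_svm(features, seed=cfg.svm_seed)
        scores = biomarker_eval.phenotype_scores(phenos)
        correlations = biomarker_eval.pearson_with_fdr(features, scores)

    demographics = group_inference.demographics_table(phenos)

    result = RunResult(
        cohort=cohort, asso_z_maps=asso_z_maps, fcs_maps=fcs_maps,
        asso_stat=asso_stat, asso_clusters=asso_clusters, seed_def=seed_def,
        fc_maps=fc_maps, fc_stat=fc_stat, fc_clusters=fc_clusters,
        features=features, report=report, correlations=correlations,
        demographics=demographics,
    )

    if out is not None:
        asso_clusters.to_frame().to_csv(out / "clusters.tsv", sep="\t", index=False)
        if fc_clusters is not None:
            fc_clusters.to_frame().to_csv(out / "fc_clusters.tsv", sep="\t",
                                          index=False)
        demographics.to_csv(out / "demographics.tsv", sep="\t", index=False)
        phenotypes_to_frame(phenos).to_csv(out / "phenotypes.tsv", sep="\t",
                                           index=False)
        if report is not None:
            with open(out / "report.json", "w") as fh:
                json.dump(report.to_dict(), fh, indent=2)
        if correlations is not None:
            correlations.to_csv(out / "corr.tsv", sep="\t", index=False)
        if features is not None:
            features.to_frame().to_csv(out / "features.tsv", sep="\t", index=False)
        _write_manifest(
            out, "run_all", cfg.to_dict(),
            {
                "asso_t": asso_stat.values,
                "clusters": asso_clusters.to_frame().to_csv(),
                "n_subjects": len(phenos),
                "_wall": round(time.time() - t0, 2),
            },
        )
    return result
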