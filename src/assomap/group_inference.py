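"""Covariate-adjusted voxelwise group inference with cluster-level correction.

The group comparison is an ordinary-least-squares fit per voxel of

    map_value ~ intercept + group + age + sex + education

with the t statistic of the group coefficient (AD=1, HC=0; covariates
mean-centred).  Clusters are formed at a two-sided voxel threshold
(p < 0.001 by default) and corrected by a group-label permutation
max-cluster-extent null — covariates stay attached to their subjects, only
the group assignment is permuted.

Also provides the summary-statistic two-sample t and the Pearson 2x2
chi-square used for demographic tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sp_stats

from .data_io import PhenotypeRecord, VoxelMap

CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class DesignMatrix:
    """n x p design with an intercept, a group indicator and covariates."""

    X: np.ndarray
    columns: list[str]
    group_col: int = 1

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise ValueError("design shape / columns mismatch")
        g = self.X[:, self.group_col]
        if np.all(g == g[0]):
            raise ValueError("group column is constant")
        rank = np.linalg.matrix_rank(self.X)
        if rank < self.X.shape[1]:
            corr = np.corrcoef(self.X[:, 1:].T)
            bad = [
                (self.columns[i + 1], self.columns[j + 1])
                for i in range(corr.shape[0])
                for j in range(i + 1, corr.shape[0])
                if abs(corr[i, j]) > 1.0 - 1e-10
            ]
            raise ValueError(f"design matrix is rank deficient; collinear: {bad}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def with_permuted_group(self, rng: np.random.Generator) -> "DesignMatrix":
        X = self.X.copy()
        X[:, self.group_col] = rng.permutation(X[:, self.group_col])
        return DesignMatrix(X=X, columns=list(self.columns),
                            group_col=self.group_col)


def build_design(
    phenotypes: Sequence[PhenotypeRecord],
    covariates: Sequence[str] = ("age", "sex", "education"),
) -> DesignMatrix:
    """Intercept + group (AD=1) + mean-centred covariates (sex coded M=1/F=0)."""
    n = len(phenotypes)
    cols = [np.ones(n), np.array([1.0 if p.group == "AD" else 0.0
                                  for p in phenotypes])]
    names = ["intercept", "group"]
    for cov in covariates:
        if cov == "sex":
            v = np.array([1.0 if p.sex == "M" else 0.0 for p in phenotypes])
        else:
            v = np.array([float(getattr(p, cov)) for p in phenotypes])
        cols.append(v - v.mean())
        names.append(cov)
    return DesignMatrix(X=np.column_stack(cols), columns=names)


@dataclass
class StatMap:
    """Voxelwise t map for one contrast."""

    values: np.ndarray
    df: int
    contrast: str
    affine: np.ndarray
    mask: np.ndarray

    def as_voxel_map(self) -> VoxelMap:
        return VoxelMap(values=self.values, affine=self.affine, kind="t",
                        mask=self.mask)


def _glm_group_t(Y: np.ndarray, design: DesignMatrix) -> tuple[np.ndarray, int]:
    """t of the group coefficient per column of Y (n x V)."""
    X = design.X
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(sigma2 * xtx_inv[design.group_col, design.group_col])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[design.group_col] / se, 0.0)
    return t, df


def voxelwise_glm_ttest(
    maps: Sequence[VoxelMap], design: DesignMatrix, mask: np.ndarray | None = None
) -> StatMap:
    """Covariate-adjusted two-sample t map over subject-level maps."""
    if len(maps) != design.n:
        raise ValueError(
            f"{len(maps)} maps but {design.n} design rows"
        )
    if mask is None:
        mask = maps[0].mask
    mask = np.asarray(mask, dtype=bool)
    for m in maps:
        if m.values.shape != mask.shape:
            raise ValueError("maps are on different grids")
    Y = np.stack([m.values[mask] for m in maps], axis=0)
    t, df = _glm_group_t(Y, design)
    values = np.zeros(mask.shape)
    values[mask] = t
    return StatMap(values=values, df=df, contrast="group:AD-HC",
                   affine=maps[0].affine, mask=mask)


@dataclass
class Cluster:
    cluster_id: int
    tail: str  # "pos" or "neg"
    extent: int
    peak_index: tuple[int, int, int]
    peak_mm: tuple[float, float, float]
    peak_t: float
    mask: np.ndarray
    corrected_p: float = np.nan


@dataclass
class ClusterTable:
    clusters: list[Cluster] = field(default_factory=list)
    t_threshold: float = np.nan
    null_max_extent: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cluster_id": c.cluster_id,
                "tail": c.tail,
                "extent": c.extent,
                "peak_x_mm": c.peak_mm[0],
                "peak_y_mm": c.peak_mm[1],
                "peak_z_mm": c.peak_mm[2],
                "peak_t": c.peak_t,
                "corrected_p": c.corrected_p,
            }
            for c in self.clusters
        ]
        return pd.DataFrame(
            rows,
            columns=["cluster_id", "tail", "extent", "peak_x_mm", "peak_y_mm",
                     "peak_z_mm", "peak_t", "corrected_p"],
        )

    def significant(self, cluster_p: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.corrected_p < cluster_p]


def _label_clusters(
    tmap: np.ndarray, mask: np.ndarray, t_threshold: float, struct: np.ndarray,
    affine: np.ndarray, two_sided: bool
) -> list[Cluster]:
    clusters: list[Cluster] = []
    tails = [("pos", tmap >= t_threshold)]
    if two_sided:
        tails.append(("neg", tmap <= -t_threshold))
    cid = 0
    for tail, supra in tails:
        supra = supra & mask
        labeled, n_lab = ndimage.label(supra, structure=struct)
        for lab in range(1, n_lab + 1):
            cmask = labeled == lab
            vals = np.where(cmask, tmap, 0.0)
            if tail == "pos":
                peak = np.unravel_index(np.argmax(vals), vals.shape)
            else:
                peak = np.unravel_index(np.argmin(vals), vals.shape)
            peak_mm = (affine @ np.array([*peak, 1.0]))[:3]
            cid += 1
            clusters.append(
                Cluster(
                    cluster_id=cid,
                    tail=tail,
                    extent=int(cmask.sum()),
                    peak_index=tuple(int(i) for i in peak),
                    peak_mm=tuple(float(x) for x in peak_mm),
                    peak_t=float(tmap[peak]),
                    mask=cmask,
                )
            )
    clusters.sort(key=lambda c: -c.extent)
    for i, c in enumerate(clusters, start=1):
        c.cluster_id = i
    return clusters


def cluster_extract(
    stat: StatMap,
    voxel_p: float = 0.001,
    two_sided: bool = True,
    connectivity: int = 18,
) -> ClusterTable:
    """Suprathreshold clusters of a t map (uncorrected).

    The cluster-forming threshold is the two-sided p<voxel_p t quantile;
    positive and negative tails are labelled separately.
    """
    if connectivity not in CONNECTIVITY_STRUCTS:
        raise ValueError("connectivity must be 6, 18 or 26")
    tail_p = voxel_p / 2.0 if two_sided else voxel_p
    t_thr = float(sp_stats.t.isf(tail_p, stat.df))
    clusters = _label_clusters(
        stat.values, stat.mask, t_thr, CONNECTIVITY_STRUCTS[connectivity],
        stat.affine, two_sided
    )
    return ClusterTable(clusters=clusters, t_threshold=t_thr)


def permutation_cluster_correction(
    maps: Sequence[VoxelMap],
    design: DesignMatrix,
    n_perm: int = 1000,
    voxel_p: float = 0.001,
    cluster_p: float = 0.05,
    two_sided: bool = True,
    connectivity: int = 18,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> tuple[StatMap, ClusterTable]:
    """Group-label permutation max-cluster-extent correction.

    corrected p = (1 + #{permutation max extent >= observed extent})
                  / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    import warnings

    if 1.0 / (n_perm + 1) > cluster_p:
        warnings.warn(
            f"n_perm={n_perm} cannot resolve p < {cluster_p}", stacklevel=2
        )
    stat = voxelwise_glm_ttest(maps, design, mask=mask)
    observed = cluster_extract(stat, voxel_p=voxel_p, two_sided=two_sided,
                               connectivity=connectivity)
    if mask is None:
        mask = maps[0].mask
    mask = np.asarray(mask, dtype=bool)
    Y = np.stack([m.values[mask] for m in maps], axis=0)
    struct = CONNECTIVITY_STRUCTS[connectivity]
    rng = np.random.default_rng(seed)
    t_thr = observed.t_threshold
    null_max = np.zeros(n_perm, dtype=np.int64)
    tvol = np.zeros(mask.shape)
    for b in range(n_perm):
        d_perm = design.with_permuted_group(rng)
        t_perm, _ = _glm_group_t(Y, d_perm)
        tvol[mask] = t_perm
        best = 0
        supra = (tvol >= t_thr) & mask
        if supra.any():
            lab, nl = ndimage.label(supra, structure=struct)
            if nl:
                best = int(np.bincount(lab.ravel())[1:].max())
        if two_sided:
            infra = (tvol <= -t_thr) & mask
            if infra.any():
                lab, nl = ndimage.label(infra, structure=struct)
                if nl:
                    best = max(best, int(np.bincount(lab.ravel())[1:].max()))
        null_max[b] = best
    for c in observed.clusters:
        c.corrected_p = float(
            (1 + np.sum(null_max >= c.extent)) / (n_perm + 1)
        )
    observed.null_max_extent = null_max
    return stat, observed


# ---------------------------------------------------------------------------
# demographic-table statistics
# ---------------------------------------------------------------------------


def summary_ttest(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t from summary statistics; two-sided p."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("sds must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (mean1 - mean2) / se
    p = 2.0 * sp_stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def chi_square_2x2(
    a: int, b: int, c: int, d: int, yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 table [[a, b], [c, d]], df = 1."""
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cell counts must be nonnegative integers")
    n = a + b + c + d
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins):
        raise ValueError("zero margin in 2x2 table")
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2.0, 0.0)
    chi2 = n * diff**2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(sp_stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def demographics_table(phenotypes: Sequence[PhenotypeRecord]) -> pd.DataFrame:
    """Group means/SDs and tests for age, education, MMSE, MoCA and sex."""
    ad = [p for p in phenotypes if p.group == "AD"]
    hc = [p for p in phenotypes if p.group == "HC"]
    rows = []
    for var in ("age", "education", "mmse", "moca"):
        x = np.array([float(getattr(p, var)) for p in ad])
        y = np.array([float(getattr(p, var)) for p in hc])
        t, df, p = summary_ttest(
            x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
        )
        rows.append({"variable": var, "ad_mean": x.mean(), "ad_sd": x.std(ddof=1),
                     "hc_mean": y.mean(), "hc_sd": y.std(ddof=1),
                     "stat": t, "df": df, "p": p, "test": "two-sample t"})
    a = sum(1 for p in ad if p.sex == "M")
    b = len(ad) - a
    c = sum(1 for p in hc if p.sex == "M")
    d = len(hc) - c
    chi2, p = chi_square_2x2(a, b, c, d)
    rows.append({"variable": "sex(M:F)", "ad_mean": a, "ad_sd": b,
                 "hc_mean": c, "hc_sd": d, "stat": chi2, "df": 1, "p": p,
                 "test": "pearson chi2"})
    return pd.DataFrame(rows)
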