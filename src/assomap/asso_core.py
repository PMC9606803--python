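"""Voxel-level association (Asso) and degree-centrality (FCS) maps.

For every in-mask voxel i, build the whole-brain thresholded correlation
graph (edge iff Pearson r > r_threshold, self excluded) and count

    N_i = degree of i (its supra-threshold neighbours),
    K_i = number of supra-threshold edges AMONG those neighbours.

The association index is

    Asso_i = (N_i * (N_i - 1) - 2 * K_i) / 2 = C(N_i, 2) - K_i,

the number of neighbour pairs NOT directly interconnected — pairs for which
voxel i is a potential mediator.  FCS (degree centrality) is N_i alone.

Asso maps are z-scored within the mask and smoothed with a 6 mm FWHM Gaussian
before group statistics; smoothing is applied to the map, never to the BOLD
series feeding the Asso computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .data_io import BoldDataset, VoxelMap

logger = logging.getLogger(__name__)

R_THRESHOLD = 0.25
FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


@dataclass
class AssoCounts:
    """Per-voxel neighbour count N, neighbour-edge count K and Asso value."""

    n_neighbors: np.ndarray
    k_edges: np.ndarray
    asso: np.ndarray


def asso_index(n_neighbors: int, k_edges: int) -> float:
    """Asso = (N(N-1) - 2K) / 2 for a single voxel."""
    n, k = int(n_neighbors), int(k_edges)
    if n < 0 or k < 0:
        raise ValueError("N and K must be nonnegative")
    max_k = n * (n - 1) // 2
    if k > max_k:
        raise ValueError(f"K={k} exceeds C(N,2)={max_k} for N={n}")
    return (n * (n - 1) - 2 * k) / 2.0


def threshold_adjacency(
    series: np.ndarray,
    r_threshold: float = R_THRESHOLD,
    use_absolute: bool = False,
) -> np.ndarray:
    """Boolean adjacency over voxel time series (V x T), self excluded.

    Edges use the signed correlation r > r_threshold by default; constant
    (zero-variance) series are never connected (their count is logged).
    """
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 2:
        raise ValueError("series must be V x T")
    v = series.shape[0]
    sd = series.std(axis=1)
    constant = sd == 0
    n_const = int(constant.sum())
    if n_const:
        logger.warning("%d constant in-mask series treated as unconnected", n_const)
    centered = series - series.mean(axis=1, keepdims=True)
    safe_sd = np.where(constant, 1.0, sd)
    normed = centered / (safe_sd[:, None] * np.sqrt(series.shape[1]))
    corr = normed @ normed.T
    if use_absolute:
        adj = np.abs(corr) > r_threshold
    else:
        adj = corr > r_threshold
    np.fill_diagonal(adj, False)
    adj[constant, :] = False
    adj[:, constant] = False
    return adj


def asso_counts_from_adjacency(
    adj: np.ndarray, block_size: int = 2048
) -> AssoCounts:
    """N, K and Asso for every node of a boolean adjacency matrix.

    K_i is the triangle count through i, obtained blockwise as
    ((A @ A) * A).sum(row) / 2 so memory stays bounded on large masks.
    """
    adj = np.asarray(adj, dtype=bool)
    v = adj.shape[0]
    if adj.shape != (v, v):
        raise ValueError("adjacency must be square")
    if np.any(adj != adj.T):
        raise ValueError("adjacency must be symmetric")
    n = adj.sum(axis=1).astype(np.int64)
    a = adj.astype(np.float64)
    k = np.empty(v, dtype=np.int64)
    for start in range(0, v, block_size):
        stop = min(start + block_size, v)
        common = a[start:stop] @ a  # common-neighbour counts
        k[start:stop] = np.rint(
            (common * a[start:stop]).sum(axis=1) / 2.0
        ).astype(np.int64)
    asso = (n * (n - 1)) // 2 - k
    return AssoCounts(n_neighbors=n, k_edges=k, asso=asso.astype(np.float64))


def compute_asso_map(
    bold: BoldDataset,
    mask: np.ndarray,
    r_threshold: float = R_THRESHOLD,
    use_absolute: bool = False,
    block_size: int = 2048,
) -> tuple[VoxelMap, AssoCounts]:
    """Whole-brain Asso map of one subject (plus the raw N/K counts)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != bold.shape3d:
        raise ValueError("mask grid does not match BOLD grid")
    if mask.sum() < 3:
        raise ValueError("need at least 3 in-mask voxels")
    series = bold.data[mask]
    adj = threshold_adjacency(series, r_threshold, use_absolute)
    counts = asso_counts_from_adjacency(adj, block_size=block_size)
    values = np.zeros(mask.shape, dtype=np.float64)
    values[mask] = counts.asso
    vmap = VoxelMap(values=values, affine=bold.affine, kind="asso", mask=mask)
    return vmap, counts


def compute_fcs_map(
    bold: BoldDataset,
    mask: np.ndarray,
    r_threshold: float = R_THRESHOLD,
    use_absolute: bool = False,
) -> VoxelMap:
    """Degree-centrality (FCS) map: N_i from the same thresholded graph."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != bold.shape3d:
        raise ValueError("mask grid does not match BOLD grid")
    if mask.sum() < 3:
        raise ValueError("need at least 3 in-mask voxels")
    adj = threshold_adjacency(bold.data[mask], r_threshold, use_absolute)
    values = np.zeros(mask.shape, dtype=np.float64)
    values[mask] = adj.sum(axis=1)
    return VoxelMap(values=values, affine=bold.affine, kind="fcs", mask=mask)


def zscore_map(vmap: VoxelMap, kind: str | None = None) -> VoxelMap:
    """Z-score within the mask: (v - mean) / sd; out-of-mask voxels untouched."""
    inside = vmap.in_mask()
    if inside.size < 2:
        raise ValueError("need at least 2 in-mask voxels to z-score")
    sd = inside.std(ddof=0)
    if sd == 0:
        raise ValueError("zero variance inside mask; cannot z-score")
    values = vmap.values.copy()
    values[vmap.mask] = (inside - inside.mean()) / sd
    if kind is None:
        kind = vmap.kind + "_z" if vmap.kind in ("asso",) else vmap.kind
    return VoxelMap(values=values, affine=vmap.affine, kind=kind, mask=vmap.mask)


def smooth_map(
    vmap: VoxelMap,
    fwhm_mm: float = 6.0,
    mode: str = "nearest",
) -> VoxelMap:
    """Separable Gaussian smoothing; sigma = FWHM / (2 sqrt(2 ln 2)) per axis.

    Voxel sizes come from the affine, so anisotropic grids get per-axis
    sigmas.  ``fwhm_mm=0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return vmap
    voxel_sizes = np.sqrt((vmap.affine[:3, :3] ** 2).sum(axis=0))
    sigmas = fwhm_mm * FWHM_TO_SIGMA / voxel_sizes
    values = ndimage.gaussian_filter(vmap.values, sigma=sigmas, mode=mode)
    return VoxelMap(values=values, affine=vmap.affine, kind=vmap.kind,
                    mask=vmap.mask)


def subject_asso_pipeline(
    bold: BoldDataset,
    mask: np.ndarray,
    r_threshold: float = R_THRESHOLD,
    fwhm_mm: float = 6.0,
    use_absolute: bool = False,
) -> dict[str, VoxelMap]:
    """Asso map -> z-score -> smooth, plus the FCS map, for one subject."""
    asso, _ = compute_asso_map(bold, mask, r_threshold, use_absolute)
    asso_z = zscore_map(asso)
    asso_z_s = smooth_map(asso_z, fwhm_mm=fwhm_mm)
    fcs = compute_fcs_map(bold, mask, r_threshold, use_absolute)
    return {"asso": asso, "asso_z": asso_z, "asso_z_s": asso_z_s, "fcs": fcs}
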