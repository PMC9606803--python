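"""Seed-based whole-brain functional connectivity with Fisher z.

The seed is the brain area showing an Asso group difference (the full
suprathreshold cluster by default; a sphere at the cluster peak is an
option).  The seed's mean time series is correlated with every in-mask voxel
and the map is Fisher z-transformed (atanh), with r clipped to
+/-(1 - 1e-7) so perfectly correlated voxels stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import BoldDataset, VoxelMap

FISHER_CLIP = 1.0 - 1e-7


@dataclass
class SeedDefinition:
    mask: np.ndarray
    label: str
    provenance: str = "explicit"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"seed {self.label!r} is empty")


def sphere_seed(
    center_mm: np.ndarray,
    radius_mm: float,
    affine: np.ndarray,
    shape: tuple[int, int, int],
    label: str = "sphere",
) -> SeedDefinition:
    """Spherical seed around a mm coordinate (e.g. a cluster peak)."""
    inv = np.linalg.inv(affine)
    idx = np.indices(shape).reshape(3, -1)
    mm = (affine @ np.vstack([idx, np.ones(idx.shape[1])]))[:3]
    dist = np.linalg.norm(mm - np.asarray(center_mm)[:, None], axis=0)
    mask = (dist <= radius_mm).reshape(shape)
    return SeedDefinition(mask=mask, label=label, provenance="sphere")


def extract_seed_series(bold: BoldDataset, seed: SeedDefinition) -> np.ndarray:
    """Frame-wise mean BOLD over the seed voxels."""
    if seed.mask.shape != bold.shape3d:
        raise ValueError("seed grid does not match BOLD grid")
    return bold.data[seed.mask].mean(axis=0)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """atanh with clipping at |r| = 1 - 1e-7."""
    return np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP))


def compute_seed_fc_map(
    bold: BoldDataset,
    seed: SeedDefinition,
    mask: np.ndarray,
) -> VoxelMap:
    """Fisher-z map of Pearson correlation between the seed mean series and
    every in-mask voxel (seed voxels included)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != bold.shape3d:
        raise ValueError("mask grid does not match BOLD grid")
    s = extract_seed_series(bold, seed)
    s = s - s.mean()
    s_sd = s.std()
    if s_sd == 0:
        raise ValueError("seed mean series is constant")
    series = bold.data[mask]
    centered = series - series.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1)
    safe = np.where(sd == 0, 1.0, sd)
    r = (centered @ s) / (safe * s_sd * bold.n_frames)
    r[sd == 0] = 0.0
    values = np.zeros(mask.shape, dtype=np.float64)
    values[mask] = fisher_z(r)
    return VoxelMap(values=values, affine=bold.affine, kind="fc_z", mask=mask)
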