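"""On-disk artifacts: BOLD volumes, tissue masks, motion tables, phenotypes, scalar maps.

All volumes are NIfTI-1 (.nii / .nii.gz) read and written through nibabel.
Motion parameters and phenotypes are tab-separated text.  Voxel indices are
0-based everywhere; millimetre coordinates are obtained through the image
affine, never stored separately.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")
PHENOTYPE_COLUMNS = ("subject_id", "group", "age", "sex", "education", "mmse", "moca")
VALID_GROUPS = ("AD", "HC")
VALID_SEX = ("M", "F")
MAP_KINDS = ("asso", "asso_z", "fcs", "fc_z", "t")


@dataclass
class BoldDataset:
    """One subject's 4-D BOLD series on a common grid.

    ``data`` is indexed (x, y, z, t) in arbitrary BOLD units; ``affine`` maps
    0-based voxel indices to mm coordinates.
    """

    subject_id: str
    data: np.ndarray
    tr_seconds: float
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(
                f"BOLD data must be 4-D (x,y,z,t); got {self.data.ndim}-D"
            )
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is singular")
        # a volume that is entirely NaN carries no usable signal
        flat = self.data.reshape(-1, self.data.shape[3])
        if np.any(np.all(np.isnan(flat), axis=0)):
            raise ValueError("BOLD series contains an all-NaN volume")

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[3])

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])

    def voxel_sizes_mm(self) -> np.ndarray:
        """Per-axis voxel edge lengths in mm, from the affine."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class MotionParams:
    """T x 6 rigid-body parameters: translations (mm) then rotations (radians)."""

    table: np.ndarray

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=np.float64)
        if self.table.ndim != 2 or self.table.shape[1] != 6:
            raise ValueError(
                f"motion table must be T x 6; got shape {self.table.shape}"
            )
        if not np.all(np.isfinite(self.table)):
            raise ValueError("motion table contains non-finite values")

    @property
    def n_frames(self) -> int:
        return int(self.table.shape[0])

    @property
    def translations(self) -> np.ndarray:
        return self.table[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.table[:, 3:]


@dataclass
class TissueMasks:
    """Boolean brain / white-matter / CSF masks on one grid (wm, csf within brain)."""

    brain: np.ndarray
    wm: np.ndarray
    csf: np.ndarray

    def __post_init__(self) -> None:
        self.brain = np.asarray(self.brain, dtype=bool)
        self.wm = np.asarray(self.wm, dtype=bool)
        self.csf = np.asarray(self.csf, dtype=bool)
        if not (self.brain.shape == self.wm.shape == self.csf.shape):
            raise ValueError("tissue masks must share one grid")
        if not self.brain.any():
            raise ValueError("brain mask is empty")
        if np.any(self.wm & ~self.brain):
            raise ValueError("wm mask extends outside brain mask")
        if np.any(self.csf & ~self.brain):
            raise ValueError("csf mask extends outside brain mask")


@dataclass
class PhenotypeRecord:
    subject_id: str
    group: str
    age: float
    sex: str
    education: float
    mmse: int
    moca: int

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValueError(
                f"unknown group label {self.group!r} for subject "
                f"{self.subject_id!r}; expected one of {VALID_GROUPS}"
            )
        if self.sex not in VALID_SEX:
            raise ValueError(
                f"unknown sex label {self.sex!r} for subject {self.subject_id!r}"
            )
        for name in ("age", "education", "mmse", "moca"):
            v = getattr(self, name)
            if v is None or not np.isfinite(float(v)):
                raise ValueError(
                    f"missing or non-finite {name} for subject {self.subject_id!r}"
                )
        self.mmse = int(self.mmse)
        self.moca = int(self.moca)


@dataclass
class VoxelMap:
    """A scalar brain map (Asso, Asso-z, FCS, FC-z or t) with its affine and mask."""

    values: np.ndarray
    affine: np.ndarray
    kind: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("VoxelMap values must be 3-D")
        if self.values.shape != self.mask.shape:
            raise ValueError("VoxelMap values and mask must share one grid")
        if self.kind not in MAP_KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("VoxelMap has non-finite values inside the mask")

    def in_mask(self) -> np.ndarray:
        """1-D view of the in-mask values (C order over the mask)."""
        return self.values[self.mask]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_motion_table(path: str | Path) -> np.ndarray:
    """Read a 6-column motion TSV; a single header row is auto-detected."""
    path = Path(path)
    first = None
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line
                break
    if first is None:
        raise ValueError(f"motion file {path} is empty")
    try:
        [float(tok) for tok in first.split()]
        skip = 0
    except ValueError:
        skip = 1
    table = np.loadtxt(path, skiprows=skip, ndmin=2)
    if table.shape[1] != 6:
        raise ValueError(
            f"motion file {path} has {table.shape[1]} columns; expected 6"
        )
    return table


def load_motion_params(path: str | Path) -> MotionParams:
    return MotionParams(_read_motion_table(path))


def save_motion_params(motion: MotionParams, path: str | Path) -> None:
    np.savetxt(path, motion.table, delimiter="\t", fmt="%.10g")


def load_bold_dataset(
    path_bold: str | Path,
    path_motion: str | Path | None = None,
    tr: float | None = None,
    subject_id: str | None = None,
) -> tuple[BoldDataset, MotionParams | None]:
    """Load a 4-D NIfTI and (optionally) its motion table.

    The affine is taken from the NIfTI header; data units are preserved.  The
    motion table must have exactly one row per volume.
    """
    path_bold = Path(path_bold)
    img = nib.load(str(path_bold))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path_bold} is {data.ndim}-D; a 4-D BOLD image is required")
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    sid = subject_id or path_bold.name.split(".")[0]
    bold = BoldDataset(subject_id=sid, data=data, tr_seconds=tr, affine=img.affine)
    motion = None
    if path_motion is not None:
        motion = load_motion_params(path_motion)
        if motion.n_frames != bold.n_frames:
            raise ValueError(
                f"length mismatch: motion table has {motion.n_frames} rows but "
                f"BOLD has {bold.n_frames} volumes"
            )
    return bold, motion


def save_bold_dataset(bold: BoldDataset, path: str | Path) -> None:
    img = nib.Nifti1Image(bold.data.astype(np.float32), bold.affine)
    img.header.set_zooms(tuple(bold.voxel_sizes_mm()) + (bold.tr_seconds,))
    nib.save(img, str(path))


def load_mask(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a mask volume; any nonzero voxel is True.  Returns (mask, affine)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"mask {path} must be 3-D")
    return data != 0, img.affine


def save_mask(mask: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def load_tissue_masks(
    path_brain: str | Path, path_wm: str | Path, path_csf: str | Path
) -> tuple[TissueMasks, np.ndarray]:
    brain, affine = load_mask(path_brain)
    wm, _ = load_mask(path_wm)
    csf, _ = load_mask(path_csf)
    return TissueMasks(brain=brain, wm=wm, csf=csf), affine


def save_voxel_map(
    vmap: VoxelMap, path: str | Path, outside: str = "zero"
) -> None:
    """Write a map as NIfTI.  Outside-mask voxels are 0 (default) or NaN."""
    out = np.array(vmap.values, dtype=np.float64)
    if outside == "zero":
        out[~vmap.mask] = 0.0
    elif outside == "nan":
        out[~vmap.mask] = np.nan
    else:
        raise ValueError("outside must be 'zero' or 'nan'")
    nib.save(nib.Nifti1Image(out, vmap.affine), str(path))


def load_voxel_map(
    path: str | Path, kind: str, mask: np.ndarray | None = None
) -> VoxelMap:
    img = nib.load(str(path))
    values = np.asanyarray(img.dataobj).astype(np.float64)
    if mask is None:
        mask = np.isfinite(values)
    return VoxelMap(values=values, affine=img.affine, kind=kind, mask=mask)


def load_phenotypes(path: str | Path) -> list[PhenotypeRecord]:
    """Read the phenotype TSV (one row per subject) with validation.

    Hard errors on unknown group labels, missing covariates and duplicated
    subject ids; the error message names the offending subject.
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    if df.empty:
        raise ValueError(f"no records in phenotype file {path}")
    missing_cols = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"phenotype file {path} missing columns: {missing_cols}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicated subject_id {dup.iloc[0]!r} in {path}")
    records = []
    for _, row in df.iterrows():
        for col in ("age", "education", "mmse", "moca"):
            if pd.isna(row[col]):
                raise ValueError(
                    f"missing covariate {col!r} for subject {row['subject_id']!r}"
                )
        records.append(
            PhenotypeRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                education=float(row["education"]),
                mmse=int(row["mmse"]),
                moca=int(row["moca"]),
            )
        )
    return records


def save_phenotypes(records: Sequence[PhenotypeRecord], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
        path, sep="\t", index=False
    )


def phenotypes_to_frame(records: Sequence[PhenotypeRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])
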