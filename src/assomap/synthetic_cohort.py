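"""Synthetic two-group resting-state cohort with planted hub / coupling effects.

The generator emulates the statistical structure the downstream analysis
assumes, on a small cubic grid:

* a set of axis-aligned cuboid "regions", each carrying a latent low-frequency
  signal shared by its voxels;
* one hub region (a stand-in for the dorsal anterior insula) whose voxels load
  on a mixture of all other region signals, so the hub correlates with many
  regions.  When the region signals are mutually weakly coupled the hub's
  neighbours are NOT interconnected (high N, low K, high Asso); raising the
  region-to-region coupling (the patient group) interconnects the hub's
  neighbourhood and collapses its Asso;
* two "default-mode" regions (stand-ins for PCC and MPFC) that, in the patient
  group, share an extra latent signal with the hub — the planted increase in
  seed functional connectivity;
* AR(1)-plus-white temporal noise, slow motion drift with optional spikes, and
  cognitive scores (MMSE/MoCA) generated as decreasing linear functions of each
  subject's realized coupling parameter.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_io import (
    BoldDataset,
    MotionParams,
    PhenotypeRecord,
    TissueMasks,
    save_bold_dataset,
    save_mask,
    save_motion_params,
    save_phenotypes,
)

# Cognitive score anchors for the two groups (means / SDs of the screening
# instruments in a typical mild-to-moderate AD cohort vs elderly controls).
MMSE_HC_MEAN, MMSE_HC_SD = 28.24, 1.43
MMSE_AD_MEAN, MMSE_AD_SD = 21.3, 3.36
MOCA_HC_MEAN, MOCA_HC_SD = 26.95, 2.01
MOCA_AD_MEAN, MOCA_AD_SD = 16.92, 3.08
AGE_AD_MEAN, AGE_AD_SD = 68.84, 7.84
AGE_HC_MEAN, AGE_HC_SD = 66.07, 6.79
EDU_AD_MEAN, EDU_AD_SD = 10.84, 3.11
EDU_HC_MEAN, EDU_HC_SD = 11.62, 3.32

# A subject whose realized neighbour coupling exceeds the control level by
# this much has severity 1 (the patient-group default); severity drives the
# hub decoupling, the seed-FC gain and the cognitive decline.
COUPLING_SEVERITY_SCALE = 0.45


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Correlation-like parameters (``base_r``, the neighbour couplings,
    ``seed_fc_gain_ad``) live in [0, 1); ``base_r`` is the within-region
    voxel-to-voxel correlation, the neighbour couplings set the correlation
    between region latents (patients > controls plants the Asso deficit), and
    ``seed_fc_gain_ad`` is the loading of the extra hub–DMN shared signal in
    the patient group.
    """

    n_ad: int = 20
    n_hc: int = 20
    grid: tuple[int, int, int] = (12, 12, 12)
    t_frames: int = 120
    tr_seconds: float = 2.0
    n_regions: int = 8
    hub_region: int = 0
    dmn_regions: tuple[int, int] = (1, 2)
    region_size: int = 3
    base_r: float = 0.8
    hub_coupling: float = 0.3
    hub_coupling_drop_ad: float = 0.9
    neighbor_coupling_ad: float = 0.5
    neighbor_coupling_hc: float = 0.05
    coupling_jitter_sd: float = 0.06
    seed_fc_gain_ad: float = 0.8
    noise_sd: float = 0.2
    ar1_phi: float = 0.3
    motion_spike_rate: float = 0.03
    motion_spike_magnitude_mm: float = 1.0
    cognitive_noise_sd: float = 1.3
    voxel_size_mm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "base_r",
            "neighbor_coupling_ad",
            "neighbor_coupling_hc",
        ):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1); got {v}")
        if not (0.0 <= self.seed_fc_gain_ad < 2.0):
            raise ValueError("seed_fc_gain_ad must be in [0, 2)")
        if self.hub_region in self.dmn_regions:
            raise ValueError("hub_region must not be one of dmn_regions")
        if self.n_ad < 2 or self.n_hc < 2:
            raise ValueError("need at least 2 subjects per group")
        if max(self.hub_region, *self.dmn_regions) >= self.n_regions:
            raise ValueError("region indices exceed n_regions")


@dataclass
class CohortTruth:
    """Ground-truth descriptors of the planted effects."""

    planted: bool
    hub_region: int
    dmn_regions: tuple[int, int]
    neighbor_coupling_ad: float
    neighbor_coupling_hc: float
    seed_fc_gain_ad: float
    direction_asso: str  # "AD<HC" or "none"
    direction_seed_fc: str  # "AD>HC" or "none"
    subject_coupling: dict[str, float] = field(default_factory=dict)
    subject_severity: dict[str, float] = field(default_factory=dict)


@dataclass
class SyntheticCohort:
    subjects: list[tuple[BoldDataset, MotionParams, PhenotypeRecord]]
    region_labels: np.ndarray  # 0 = background, r+1 = region r
    masks: TissueMasks
    affine: np.ndarray
    truth: CohortTruth

    def region_mask(self, region: int) -> np.ndarray:
        return self.region_labels == region + 1

    @property
    def phenotypes(self) -> list[PhenotypeRecord]:
        return [p for _, _, p in self.subjects]


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def make_region_layout(cfg: CohortConfig) -> tuple[np.ndarray, TissueMasks, np.ndarray]:
    """Place cuboid regions inside a box-shaped brain mask.

    Regions are ``region_size``-cubes at the corners of the inner brain box
    (up to 8), laid out deterministically.  The WM and CSF masks are small
    cubes in the region-free centre of the box.
    """
    nx, ny, nz = cfg.grid
    s = cfg.region_size
    if min(cfg.grid) < 2 * s + 2 + 2:
        raise ValueError(
            f"grid {cfg.grid} too small for two {s}-cubes per axis plus margins"
        )
    if cfg.n_regions > 8:
        raise ValueError("at most 8 corner regions are supported")
    labels = np.zeros(cfg.grid, dtype=np.int16)
    brain = np.zeros(cfg.grid, dtype=bool)
    brain[1 : nx - 1, 1 : ny - 1, 1 : nz - 1] = True
    lo = 1
    hi = {0: nx - 1 - s, 1: ny - 1 - s, 2: nz - 1 - s}
    corners = [
        (a, b, c) for a in (lo, hi[0]) for b in (lo, hi[1]) for c in (lo, hi[2])
    ]
    for r in range(cfg.n_regions):
        x0, y0, z0 = corners[r]
        block = labels[x0 : x0 + s, y0 : y0 + s, z0 : z0 + s]
        if np.any(block != 0):
            raise ValueError("region placement overlaps an existing region")
        labels[x0 : x0 + s, y0 : y0 + s, z0 : z0 + s] = r + 1
    if np.any((labels > 0) & ~brain):
        raise ValueError("regions overflow the brain mask")
    cx, cy, cz = nx // 2, ny // 2, nz // 2
    wm = np.zeros(cfg.grid, dtype=bool)
    csf = np.zeros(cfg.grid, dtype=bool)
    wm[cx - 1 : cx + 1, cy - 1 : cy + 1, cz - 1 : cz + 1] = True
    csf[cx - 1 : cx + 1, cy - 1 : cy + 1, cz + 1 : cz + 3] = True
    wm &= brain & (labels == 0)
    csf &= brain & (labels == 0)
    if not wm.any() or not csf.any():
        raise ValueError("grid too small to place WM/CSF masks")
    masks = TissueMasks(brain=brain, wm=wm, csf=csf)
    affine = np.diag([cfg.voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -cfg.voxel_size_mm * (np.array(cfg.grid) - 1) / 2.0
    return labels, masks, affine


# ---------------------------------------------------------------------------
# temporal building blocks
# ---------------------------------------------------------------------------


def _ar1(rng: np.random.Generator, t: int, phi: float, size: int = 1) -> np.ndarray:
    """Standardized AR(1) series, shape (size, t)."""
    eps = rng.standard_normal((size, t))
    out = np.empty_like(eps)
    out[:, 0] = eps[:, 0]
    for i in range(1, t):
        out[:, i] = phi * out[:, i - 1] + eps[:, i]
    out -= out.mean(axis=1, keepdims=True)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_motion(
    t_frames: int,
    spike_rate: float = 0.03,
    spike_magnitude_mm: float = 1.0,
    seed: int = 0,
) -> MotionParams:
    """Smooth low-amplitude drift plus Bernoulli displacement spikes.

    A spike offsets the x-translation of a single frame by
    ``spike_magnitude_mm`` (and returns), so framewise displacement exceeds
    the magnitude at the spiked frame and the one after it.
    """
    if not (0.0 <= spike_rate < 1.0):
        raise ValueError("spike_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    trans = np.cumsum(rng.normal(0.0, 0.008, size=(t_frames, 3)), axis=0)
    rot = np.cumsum(rng.normal(0.0, 0.00015, size=(t_frames, 3)), axis=0)
    table = np.hstack([trans, rot])
    # spikes never on frame 0 (FD of the first frame is defined as 0)
    spikes = rng.random(t_frames) < spike_rate
    spikes[0] = False
    table[spikes, 0] += spike_magnitude_mm
    return MotionParams(table)


def planted_spike_frames(motion: MotionParams, magnitude_mm: float) -> np.ndarray:
    """Recover the frames spiked by :func:`simulate_motion` (for bookkeeping)."""
    dx = np.abs(np.diff(motion.table[:, 0]))
    hits = np.flatnonzero(dx > 0.5 * magnitude_mm)
    # each single-frame spike produces two large deltas (up at t, down at t+1)
    return np.unique([h + 1 for h in hits if (h + 1) < motion.n_frames and
                      motion.table[h + 1, 0] - motion.table[h, 0] > 0])


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def _subject_bold(
    rng: np.random.Generator,
    cfg: CohortConfig,
    labels: np.ndarray,
    brain: np.ndarray,
    coupling: float,
    fc_gain: float,
    severity: float = 0.0,
) -> np.ndarray:
    """Build one subject's (x,y,z,t) BOLD array from the latent-signal model."""
    t = cfg.t_frames
    R = cfg.n_regions
    hub_sig = _ar1(rng, t, cfg.ar1_phi)[0]  # the hub's own latent
    shared = _ar1(rng, t, cfg.ar1_phi)[0]  # the neighbour-coupling factor
    fc_latent = _ar1(rng, t, cfg.ar1_phi)[0]  # the extra hub-DMN signal (AD)
    latent_raw = _ar1(rng, t, cfg.ar1_phi, size=R)

    # Each non-hub region loads on the hub latent (weight sqrt(hub_coupling))
    # and on the coupling factor (weight sqrt(coupling)).  Both loadings are
    # sign-balanced across regions (anticorrelated-network style) so neither
    # factor dominates the global mean and the planted structure survives
    # global-signal regression.  The hub's supra-threshold neighbours are the
    # regions with positive hub loading; raising ``coupling`` interconnects
    # the same-sign pairs among them (the K effect).  The DMN stand-ins load
    # NEGATIVELY on the hub latent — the task-negative anticorrelation — so
    # they are never hub neighbours; in patients the extra shared signal
    # lifts hub-DMN connectivity from anticorrelated toward positive (the
    # planted seed-FC increase) without touching the hub's neighbour count.
    others = [r for r in range(R) if r != cfg.hub_region]
    s_hub = {}  # sign of the hub-latent loading
    s_cpl = {}  # sign of the coupling-factor loading
    dmn = [r for r in cfg.dmn_regions if r in others]
    rest = [r for r in others if r not in dmn]
    half = (len(others) + 1) // 2
    for r in dmn:
        s_hub[r] = -1.0
        s_cpl[r] = 1.0
    n_pos_cpl = len(dmn)
    for r in rest:
        s_cpl[r] = 1.0 if n_pos_cpl < half else -1.0
        n_pos_cpl += 1 if s_cpl[r] > 0 else 0
    # hub signs for the remaining regions: fill the positive half first
    # (interleaved with the coupling signs) so the partitions differ
    n_pos_hub = 0
    for r in sorted(rest, key=lambda r: s_cpl[r]):
        s_hub[r] = 1.0 if n_pos_hub < half else -1.0
        n_pos_hub += 1 if s_hub[r] > 0 else 0

    # the same severity parameter that raises the neighbour coupling also
    # weakens the hub-to-region coupling, so patients lose hub neighbours (N)
    # while the surviving neighbours interconnect (K).  The DMN stand-ins are
    # exempt from the drop: their (negative) hub coupling stays put.
    m0 = min(cfg.hub_coupling, 0.95)
    m_drop = m0 * (
        1.0 - cfg.hub_coupling_drop_ad * float(np.clip(severity, 0.0, 1.2))
    )
    m_drop = max(m_drop, 0.0)
    region_sig = np.empty((R, t))
    for r in range(R):
        if r == cfg.hub_region:
            region_sig[r] = hub_sig
            continue
        m = m0 if r in cfg.dmn_regions else m_drop
        c = min(coupling, 0.95 - m)
        resid = max(1.0 - c - m, 0.0)
        region_sig[r] = (
            np.sqrt(resid) * latent_raw[r]
            + s_cpl[r] * np.sqrt(c) * shared
            + s_hub[r] * np.sqrt(m) * hub_sig
        )
        region_sig[r] = _standardize(region_sig[r])

    hub_latent = hub_sig
    if fc_gain > 0:
        hub_latent = _standardize(hub_sig + fc_gain * fc_latent)
        for r in cfg.dmn_regions:
            region_sig[r] = _standardize(region_sig[r] + fc_gain * fc_latent)

    data = np.zeros(cfg.grid + (t,), dtype=np.float64)
    flat_labels = labels.reshape(-1)
    flat_brain = brain.reshape(-1)
    flat = data.reshape(-1, t)
    n_vox = flat.shape[0]
    noise = _ar1(rng, t, cfg.ar1_phi, size=int(flat_brain.sum()))
    white = rng.standard_normal((int(flat_brain.sum()), t))
    a = np.sqrt(cfg.base_r)
    b = np.sqrt(1.0 - cfg.base_r)
    brain_idx = np.flatnonzero(flat_brain)
    sig = np.zeros((len(brain_idx), t))
    lab = flat_labels[brain_idx]
    for r in range(R):
        sel = lab == r + 1
        if not np.any(sel):
            continue
        src = hub_latent if r == cfg.hub_region else region_sig[r]
        sig[sel] = a * src
    # background voxels carry no latent loading; their "signal" term is zero
    series = sig + np.where(lab[:, None] > 0, b, 1.0) * noise
    series = series + cfg.noise_sd * white
    flat[brain_idx] = 1000.0 + 50.0 * series
    return flat.reshape(cfg.grid + (t,))


def _cognitive_scores(
    rng: np.random.Generator, severity: float, noise_sd: float
) -> tuple[int, int]:
    mmse = MMSE_HC_MEAN - (MMSE_HC_MEAN - MMSE_AD_MEAN) * severity
    moca = MOCA_HC_MEAN - (MOCA_HC_MEAN - MOCA_AD_MEAN) * severity
    mmse += rng.normal(0.0, noise_sd)
    moca += rng.normal(0.0, noise_sd)
    return (
        int(np.clip(round(mmse), 0, 30)),
        int(np.clip(round(moca), 0, 30)),
    )


def simulate_cohort(cfg: CohortConfig) -> SyntheticCohort:
    """Generate the full two-group cohort (BOLD + motion + phenotypes + truth)."""
    labels, masks, affine = make_region_layout(cfg)
    root = np.random.SeedSequence(cfg.seed)
    groups = ["AD"] * cfg.n_ad + ["HC"] * cfg.n_hc
    n = len(groups)
    child_seeds = root.spawn(n + 1)
    meta_rng = np.random.default_rng(child_seeds[-1])

    dc = cfg.neighbor_coupling_ad - cfg.neighbor_coupling_hc
    planted = (abs(dc) > 1e-12) or (cfg.seed_fc_gain_ad > 0)
    truth = CohortTruth(
        planted=planted,
        hub_region=cfg.hub_region,
        dmn_regions=cfg.dmn_regions,
        neighbor_coupling_ad=cfg.neighbor_coupling_ad,
        neighbor_coupling_hc=cfg.neighbor_coupling_hc,
        seed_fc_gain_ad=cfg.seed_fc_gain_ad,
        direction_asso="AD<HC" if dc > 1e-12 else "none",
        direction_seed_fc="AD>HC" if cfg.seed_fc_gain_ad > 0 else "none",
    )

    subjects = []
    for i, group in enumerate(groups):
        rng = np.random.default_rng(child_seeds[i])
        sid = f"sub-{i + 1:03d}"
        target = (
            cfg.neighbor_coupling_ad if group == "AD" else cfg.neighbor_coupling_hc
        )
        coupling = float(
            np.clip(rng.normal(target, cfg.coupling_jitter_sd), 0.0, 0.95)
        )
        if abs(dc) > 1e-12:
            # the subject's realized coupling is the hub-Asso-driving parameter
            severity = float(np.clip(
                (coupling - cfg.neighbor_coupling_hc) / COUPLING_SEVERITY_SCALE,
                0.0, 1.2,
            ))
            fc_severity = severity
        elif cfg.seed_fc_gain_ad > 0:
            # no coupling contrast: the FC effect (and cognition) follow group
            severity = 0.0
            fc_severity = 1.0 if group == "AD" else 0.0
        else:
            severity = fc_severity = 0.0
        fc_gain = cfg.seed_fc_gain_ad * float(np.clip(fc_severity, 0.0, 1.5))
        data = _subject_bold(rng, cfg, labels, masks.brain, coupling, fc_gain,
                             severity=float(np.clip(severity, 0.0, 1.2)))
        bold = BoldDataset(
            subject_id=sid, data=data, tr_seconds=cfg.tr_seconds, affine=affine
        )
        motion = simulate_motion(
            cfg.t_frames,
            spike_rate=cfg.motion_spike_rate,
            spike_magnitude_mm=cfg.motion_spike_magnitude_mm,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        if group == "AD":
            age = rng.normal(AGE_AD_MEAN, AGE_AD_SD)
            edu = rng.normal(EDU_AD_MEAN, EDU_AD_SD)
        else:
            age = rng.normal(AGE_HC_MEAN, AGE_HC_SD)
            edu = rng.normal(EDU_HC_MEAN, EDU_HC_SD)
        mmse, moca = _cognitive_scores(
            rng, max(severity, fc_severity), cfg.cognitive_noise_sd
        )
        pheno = PhenotypeRecord(
            subject_id=sid,
            group=group,
            age=float(np.clip(age, 50, 95)),
            sex="M" if meta_rng.random() < 0.5 else "F",
            education=float(np.clip(edu, 0, 25)),
            mmse=mmse,
            moca=moca,
        )
        truth.subject_coupling[sid] = coupling
        truth.subject_severity[sid] = float(severity)
        subjects.append((bold, motion, pheno))

    return SyntheticCohort(
        subjects=subjects,
        region_labels=labels,
        masks=masks,
        affine=affine,
        truth=truth,
    )


def simulate_null_cohort(cfg: CohortConfig) -> SyntheticCohort:
    """Cohort with every group-difference parameter forced to zero.

    All subjects share the control coupling level and zero seed-FC gain;
    group labels are a random permutation (sizes kept), so any detected group
    difference is a false positive.
    """
    null_cfg = dataclasses.replace(
        cfg,
        neighbor_coupling_ad=cfg.neighbor_coupling_hc,
        seed_fc_gain_ad=0.0,
    )
    cohort = simulate_cohort(null_cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5EED]))
    groups = ["AD"] * cfg.n_ad + ["HC"] * cfg.n_hc
    perm = rng.permutation(len(groups))
    for i, (bold, motion, pheno) in enumerate(cohort.subjects):
        pheno.group = groups[perm[i]]
    cohort.truth.planted = False
    cohort.truth.direction_asso = "none"
    cohort.truth.direction_seed_fc = "none"
    return cohort


# ---------------------------------------------------------------------------
# on-disk cohort
# ---------------------------------------------------------------------------


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write per-subject NIfTI + motion TSV, phenotypes.tsv, masks and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for bold, motion, pheno in cohort.subjects:
        save_bold_dataset(bold, outdir / f"{pheno.subject_id}_bold.nii.gz")
        save_motion_params(motion, outdir / f"{pheno.subject_id}_motion.tsv")
    save_phenotypes(cohort.phenotypes, outdir / "phenotypes.tsv")
    save_mask(cohort.masks.brain, cohort.affine, outdir / "mask_brain.nii.gz")
    save_mask(cohort.masks.wm, cohort.affine, outdir / "mask_wm.nii.gz")
    save_mask(cohort.masks.csf, cohort.affine, outdir / "mask_csf.nii.gz")
    labels_img = cohort.region_labels.astype(np.int16)
    save_mask(labels_img != 0, cohort.affine, outdir / "mask_regions.nii.gz")
    import nibabel as nib

    nib.save(
        nib.Nifti1Image(labels_img, cohort.affine), str(outdir / "region_labels.nii.gz")
    )
    truth = dataclasses.asdict(cohort.truth)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
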