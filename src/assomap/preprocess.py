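"""Temporal preprocessing of BOLD series.

Pipeline order (the default branch used for Asso mapping):

    drop initial volumes -> scrub plan from FD on the full motion trace ->
    linear detrend -> nuisance regression (Friston-24 + WM/CSF/global) ->
    zero-phase band-pass (0.01-0.1 Hz) -> scrub interpolation

Scrub interpolation is applied after filtering; frames whose framewise
displacement (FD) meets the 0.5 mm criterion are replaced, together with the
two frames before and one after, by linear interpolation between the nearest
clean frames, so the frame count never changes.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .data_io import BoldDataset, MotionParams, TissueMasks

logger = logging.getLogger(__name__)

FD_THRESHOLD_MM = 0.5
SCRUB_BEFORE = 2
SCRUB_AFTER = 1
ROTATION_RADIUS_MM = 50.0


@dataclass
class NuisanceMatrix:
    """T x R nuisance regressors with column labels."""

    matrix: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.labels):
            raise ValueError("nuisance matrix / labels mismatch")


@dataclass
class ScrubPlan:
    fd: np.ndarray
    flagged: np.ndarray
    threshold: float = FD_THRESHOLD_MM
    n_before: int = SCRUB_BEFORE
    n_after: int = SCRUB_AFTER

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=np.float64)
        self.flagged = np.asarray(self.flagged, dtype=bool)
        if self.fd.shape != self.flagged.shape:
            raise ValueError("fd and flagged must have equal length")

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())


def drop_initial_volumes(
    bold: BoldDataset, motion: MotionParams | None = None, n_drop: int = 10
) -> tuple[BoldDataset, MotionParams | None]:
    """Discard the first ``n_drop`` volumes (magnetization equilibrium).

    The motion table, when given, is cropped identically.
    """
    if n_drop < 0:
        raise ValueError("n_drop must be >= 0")
    if bold.n_frames <= n_drop:
        raise ValueError(
            f"cannot drop {n_drop} volumes from a series of {bold.n_frames}"
        )
    if n_drop == 0:
        return bold, motion
    out = dataclasses.replace(bold, data=bold.data[..., n_drop:])
    if out.n_frames < 20:
        logger.warning(
            "only %d frames remain after dropping %d", out.n_frames, n_drop
        )
    motion_out = None
    if motion is not None:
        motion_out = MotionParams(motion.table[n_drop:])
    return out, motion_out


def compute_fd(
    motion: MotionParams, rotation_radius_mm: float = ROTATION_RADIUS_MM
) -> np.ndarray:
    """Framewise displacement (mm), Power convention.

    FD_0 = 0; FD_t = sum |delta translation| + radius * sum |delta rotation|.
    """
    if motion.n_frames < 2:
        raise ValueError("need at least 2 frames to compute FD")
    d = np.abs(np.diff(motion.table, axis=0))
    fd = d[:, :3].sum(axis=1) + rotation_radius_mm * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def friston24_expand(motion: MotionParams) -> np.ndarray:
    """24 motion regressors: [p_t, p_{t-1}, p_t^2, p_{t-1}^2] per parameter.

    The lag terms are backfilled with 0 at the first frame.
    """
    p = motion.table
    lag = np.vstack([np.zeros((1, 6)), p[:-1]])
    return np.hstack([p, lag, p**2, lag**2])


def build_nuisance_matrix(
    bold: BoldDataset, masks: TissueMasks, motion: MotionParams
) -> NuisanceMatrix:
    """Friston-24 + frame-wise WM / CSF / global-mean signals (27 columns)."""
    if bold.shape3d != masks.brain.shape:
        raise ValueError("BOLD and masks are on different grids")
    if motion.n_frames != bold.n_frames:
        raise ValueError(
            f"length mismatch: motion {motion.n_frames} vs BOLD {bold.n_frames}"
        )
    flat = bold.data.reshape(-1, bold.n_frames)
    cols, labels = [], []
    for name, mask in (("wm_mean", masks.wm), ("csf_mean", masks.csf),
                       ("global_mean", masks.brain)):
        if not mask.any():
            raise ValueError(f"{name} mask is empty")
        cols.append(flat[mask.reshape(-1)].mean(axis=0))
        labels.append(name)
    friston = friston24_expand(motion)
    mat = np.column_stack(cols + [friston])
    labels += [f"friston24_{i:02d}" for i in range(24)]
    return NuisanceMatrix(matrix=mat, labels=labels)


def _drop_collinear(X: np.ndarray, labels: list[str]) -> tuple[np.ndarray, list[str]]:
    """Drop columns that are (numerically) linear combinations of earlier ones."""
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=1e-8 * max(1.0, np.abs(cand).max())) == len(keep) + 1:
            keep.append(j)
        else:
            logger.warning("dropping collinear nuisance column %r", labels[j])
    return X[:, keep], [labels[k] for k in keep]


def bandpass_filter(
    data: np.ndarray,
    tr_seconds: float,
    band: tuple[float, float] = (0.01, 0.1),
    method: str = "butter",
) -> np.ndarray:
    """Zero-phase band-pass along the last axis.

    ``butter`` is a forward-backward order-2 Butterworth; ``fft`` is an ideal
    rectangular filter in the frequency domain.
    """
    lo, hi = band
    nyq = 1.0 / (2.0 * tr_seconds)
    if not (0.0 < lo < hi < nyq):
        raise ValueError(f"band {band} must lie within (0, Nyquist={nyq:g})")
    if method == "butter":
        sos = sp_signal.butter(2, [lo / nyq, hi / nyq], btype="band", output="sos")
        return sp_signal.sosfiltfilt(sos, data, axis=-1)
    if method == "fft":
        t = data.shape[-1]
        freqs = np.fft.rfftfreq(t, d=tr_seconds)
        spec = np.fft.rfft(data, axis=-1)
        keep = (freqs >= lo) & (freqs <= hi)
        spec[..., ~keep] = 0.0
        return np.fft.irfft(spec, n=t, axis=-1)
    raise ValueError(f"unknown filter method {method!r}")


def ols_residualize(
    data: np.ndarray, nuisance: NuisanceMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """OLS residuals of each row of ``data`` (V x T) against the nuisance columns.

    The nuisance columns are detrended (their linear trend is already removed
    from the data) and an intercept is prepended; collinear columns are
    dropped with a logged warning.  Returns (residuals, retained design).
    """
    t = data.shape[-1]
    X = np.column_stack([np.ones(t), sp_signal.detrend(nuisance.matrix, axis=0)])
    labels = ["intercept"] + list(nuisance.labels)
    X, _ = _drop_collinear(X, labels)
    beta, *_ = np.linalg.lstsq(X, data.T, rcond=None)
    return data - (X @ beta).T, X


def detrend_filter_regress(
    bold: BoldDataset,
    nuisance: NuisanceMatrix | None,
    band: tuple[float, float] = (0.01, 0.1),
    filter_method: str = "butter",
) -> BoldDataset:
    """Linear detrend, nuisance OLS regression, zero-phase band-pass.

    Output series are mean-zero per voxel.  A singular nuisance matrix is
    handled by dropping collinear columns with a logged warning.
    """
    t = bold.n_frames
    flat = bold.data.reshape(-1, t)
    out = sp_signal.detrend(flat, axis=-1, type="linear")
    if nuisance is not None:
        out, _ = ols_residualize(out, nuisance)
    out = bandpass_filter(out, bold.tr_seconds, band=band, method=filter_method)
    out = out - out.mean(axis=-1, keepdims=True)
    return dataclasses.replace(bold, data=out.reshape(bold.data.shape))


def make_scrub_plan(
    fd: np.ndarray,
    threshold: float = FD_THRESHOLD_MM,
    n_before: int = SCRUB_BEFORE,
    n_after: int = SCRUB_AFTER,
) -> ScrubPlan:
    """Flag frames with FD >= threshold, expanded by the scrub window."""
    fd = np.asarray(fd, dtype=np.float64)
    bad = fd >= threshold
    flagged = bad.copy()
    for t in np.flatnonzero(bad):
        flagged[max(0, t - n_before) : t + n_after + 1] = True
    return ScrubPlan(fd=fd, flagged=flagged, threshold=threshold,
                     n_before=n_before, n_after=n_after)


def scrub_interpolate(bold: BoldDataset, plan: ScrubPlan) -> BoldDataset:
    """Replace flagged frames by linear interpolation between clean neighbours.

    Leading/trailing flagged runs are filled by nearest-value extension.  The
    frame count is unchanged; with nothing flagged the data is returned
    bitwise-identical.
    """
    if plan.flagged.shape[0] != bold.n_frames:
        raise ValueError("scrub plan length does not match BOLD frames")
    if not plan.flagged.any():
        return bold
    good = np.flatnonzero(~plan.flagged)
    if len(good) < 2:
        raise ValueError("fewer than 2 clean frames; cannot interpolate")
    t = bold.n_frames
    flat = bold.data.reshape(-1, t).copy()
    bad = np.flatnonzero(plan.flagged)
    # np.interp over the time axis: nearest-value extension at the edges comes
    # for free from its constant extrapolation
    interp_w = np.interp(bad, good, np.arange(len(good), dtype=float))
    left = np.clip(np.floor(interp_w).astype(int), 0, len(good) - 1)
    right = np.clip(left + 1, 0, len(good) - 1)
    frac = interp_w - left
    gl, gr = good[left], good[right]
    flat[:, bad] = (1.0 - frac) * flat[:, gl] + frac * flat[:, gr]
    return dataclasses.replace(bold, data=flat.reshape(bold.data.shape))


def excessive_motion(motion: MotionParams, min_voxel_size_mm: float,
                     rotation_radius_mm: float = ROTATION_RADIUS_MM) -> bool:
    """Subject-level exclusion rule: peak displacement above one voxel."""
    max_trans = np.abs(motion.translations).max()
    max_rot_mm = np.abs(motion.rotations).max() * rotation_radius_mm
    return bool(max_trans > min_voxel_size_mm or max_rot_mm > min_voxel_size_mm)


def preprocess_subject(
    bold: BoldDataset,
    motion: MotionParams,
    masks: TissueMasks,
    n_drop: int = 10,
    band: tuple[float, float] = (0.01, 0.1),
    fd_threshold: float = FD_THRESHOLD_MM,
    scrub_window: tuple[int, int] = (SCRUB_BEFORE, SCRUB_AFTER),
    filter_method: str = "butter",
    global_signal: bool = True,
    scrub_before_filter: bool = False,
) -> tuple[BoldDataset, ScrubPlan]:
    """Run the full temporal pipeline on one subject.

    Returns the cleaned series and the scrub plan actually applied.
    """
    bold, motion = drop_initial_volumes(bold, motion, n_drop=n_drop)
    fd = compute_fd(motion)
    plan = make_scrub_plan(fd, threshold=fd_threshold,
                           n_before=scrub_window[0], n_after=scrub_window[1])
    nuis = build_nuisance_matrix(bold, masks, motion)
    if not global_signal:
        keep = [i for i, l in enumerate(nuis.labels) if l != "global_mean"]
        nuis = NuisanceMatrix(nuis.matrix[:, keep],
                              [nuis.labels[i] for i in keep])
    if scrub_before_filter:
        bold = scrub_interpolate(bold, plan)
        bold = detrend_filter_regress(bold, nuis, band=band,
                                      filter_method=filter_method)
    else:
        bold = detrend_filter_regress(bold, nuis, band=band,
                                      filter_method=filter_method)
        bold = scrub_interpolate(bold, plan)
    return bold, plan
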