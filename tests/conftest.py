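"""Shared fixtures: small synthetic inputs built in memory."""

from __future__ import annotations

import numpy as np
import pytest

from assomap.data_io import BoldDataset, MotionParams, PhenotypeRecord, TissueMasks
from assomap.synthetic_cohort import CohortConfig, make_region_layout


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid_affine():
    aff = np.diag([3.0, 3.0, 3.0, 1.0])
    aff[:3, 3] = -16.5
    return aff


@pytest.fixture
def small_bold(rng, small_grid_affine):
    """12x12x12x60 noise BOLD dataset."""
    data = 1000.0 + 10.0 * rng.standard_normal((12, 12, 12, 60))
    return BoldDataset(
        subject_id="sub-001", data=data, tr_seconds=2.0, affine=small_grid_affine
    )


@pytest.fixture
def small_masks():
    brain = np.zeros((12, 12, 12), dtype=bool)
    brain[1:11, 1:11, 1:11] = True
    wm = np.zeros_like(brain)
    wm[5:7, 5:7, 5:7] = True
    csf = np.zeros_like(brain)
    csf[5:7, 5:7, 7:9] = True
    return TissueMasks(brain=brain, wm=wm, csf=csf)


@pytest.fixture
def zero_motion():
    return MotionParams(np.zeros((60, 6)))


@pytest.fixture
def tiny_cohort_cfg():
    """Fast cohort for smoke tests (8 subjects, short series)."""
    return CohortConfig(n_ad=4, n_hc=4, t_frames=60, seed=11)


@pytest.fixture
def demo_phenotypes(rng):
    """78 records shaped like the study cohort: 36 patients, 42 controls."""
    records = []
    for i in range(78):
        group = "AD" if i < 36 else "HC"
        records.append(
            PhenotypeRecord(
                subject_id=f"sub-{i + 1:03d}",
                group=group,
                age=float(rng.normal(68 if group == "AD" else 66, 7)),
                sex="M" if rng.random() < 0.5 else "F",
                education=float(rng.normal(11, 3)),
                mmse=int(rng.integers(15, 30)) if group == "AD" else int(rng.integers(26, 31)),
                moca=int(rng.integers(10, 25)) if group == "AD" else int(rng.integers(24, 31)),
            )
        )
    return records
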