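"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from socialmvpa import (
    BetaPatterns,
    CohortSpec,
    GeometryParams,
    ROISpec,
    simulate_cohort,
)


def make_patterns(values: np.ndarray, name: str = "toy", network: str = "DN") -> BetaPatterns:
    """Wrap a raw (8, n_runs, n_voxels) array as BetaPatterns."""
    values = np.asarray(values, dtype=float)
    roi = ROISpec(name=name, network=network, n_voxels=values.shape[2])
    return BetaPatterns(values=values, roi=roi, subject_id="sub-01")


def noiseless_roi(n_voxels: int = 16, info_scale: float = 1.0, network: str = "DN") -> ROISpec:
    return ROISpec(
        name="clean",
        network=network,
        n_voxels=n_voxels,
        info_scale=info_scale,
        noise_sd_run=0.0,
        noise_sd_voxel=0.0,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-subject, 4-ROI cohort with the default planted geometry."""
    rois = (
        ROISpec("PCC", "DN", n_voxels=60, info_scale=1.0),
        ROISpec("vmPFC", "DN", n_voxels=60, info_scale=1.0),
        ROISpec("lATL", "SN", n_voxels=60, info_scale=0.45),
        ROISpec("lIFG", "SN", n_voxels=60, info_scale=0.45),
    )
    spec = CohortSpec(n_subjects=6, n_runs=8, rois=rois, geometry=GeometryParams(seed=11))
    return simulate_cohort(spec)
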