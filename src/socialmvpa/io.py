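"""Reading and writing cohorts, ratings, volumes and result tables.

Cohorts are stored as one CSV per subject/ROI (columns ``person, valence,
run, voxel_0..voxel_{V-1}``) plus a JSON manifest holding the generating
spec, seeds and package version.  Volumes are stored as NIfTI (4-D betas,
3-D mask) with an identity affine scaled by the voxel size; planted truth
centers live in the manifest.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    BetaPatterns,
    Cohort,
    CohortSpec,
    RatingMatrix,
    VolumeDataset,
)
from .labels import CONDITIONS, Person, Valence

MANIFEST_NAME = "manifest.json"


def _pattern_frame(patterns: BetaPatterns) -> pd.DataFrame:
    rows = []
    for cond in CONDITIONS:
        for run in range(patterns.n_runs):
            row = {
                "person": cond.person.label,
                "valence": cond.valence.label,
                "run": run,
            }
            row.update(
                {
                    f"voxel_{v}": patterns.values[cond.index, run, v]
                    for v in range(patterns.n_voxels)
                }
            )
            rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write the cohort as per-subject/ROI CSVs plus a JSON manifest.

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    for (subject_id, roi_name), patterns in sorted(cohort.patterns.items()):
        fname = f"{subject_id}_{roi_name}.csv"
        _pattern_frame(patterns).to_csv(out_dir / fname, index=False)
        files[f"{subject_id}/{roi_name}"] = fname
    manifest = {
        "format": "socialmvpa-cohort",
        "version": __version__,
        "spec": cohort.spec.to_dict(),
        "files": files,
    }
    path = out_dir / MANIFEST_NAME
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def read_cohort(manifest_path: str | Path) -> Cohort:
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / MANIFEST_NAME
    manifest = json.loads(manifest_path.read_text())
    spec = CohortSpec.from_dict(manifest["spec"])
    base = manifest_path.parent
    patterns = {}
    for key, fname in manifest["files"].items():
        subject_id, roi_name = key.split("/")
        frame = pd.read_csv(base / fname)
        voxel_cols = [c for c in frame.columns if c.startswith("voxel_")]
        n_runs = frame["run"].max() + 1
        values = np.empty((len(CONDITIONS), n_runs, len(voxel_cols)))
        for _, row in frame.iterrows():
            cond_index = (
                int(Person.from_label(row["person"])) * 2
                + int(Valence.from_label(row["valence"]))
            )
            values[cond_index, int(row["run"])] = row[voxel_cols].to_numpy(float)
        patterns[(subject_id, roi_name)] = BetaPatterns(
            values=values, roi=spec.roi(roi_name), subject_id=subject_id
        )
    return Cohort(spec=spec, patterns=patterns)


def write_ratings(ratings: Mapping[str, RatingMatrix], path: str | Path) -> Path:
    rows = []
    for subject_id, mat in sorted(ratings.items()):
        for a in Person:
            for b in Person:
                if a < b:
                    rows.append(
                        {
                            "subject": subject_id,
                            "person_a": a.label,
                            "person_b": b.label,
                            "rating": mat.values[int(a), int(b)],
                        }
                    )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_ratings(path: str | Path) -> dict[str, RatingMatrix]:
    frame = pd.read_csv(path)
    out = {}
    for subject_id, group in frame.groupby("subject"):
        values = np.full((4, 4), 100.0)
        for _, row in group.iterrows():
            a = int(Person.from_label(row["person_a"]))
            b = int(Person.from_label(row["person_b"]))
            values[a, b] = values[b, a] = row["rating"]
        out[str(subject_id)] = RatingMatrix(values=values, subject_id=str(subject_id))
    return out


# --------------------------------------------------------------------------- #
# NIfTI
# --------------------------------------------------------------------------- #


def _affine(voxel_size_mm: float) -> np.ndarray:
    return np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])


def save_nifti(values: np.ndarray, path: str | Path, voxel_size_mm: float = 3.0) -> Path:
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float64), _affine(voxel_size_mm))
    nib.save(img, str(path))
    return Path(path)


def load_nifti(path: str | Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    voxel_size = float(abs(img.affine[0, 0]))
    return np.asarray(img.get_fdata()), voxel_size


def write_volume(volume: VolumeDataset, out_dir: str | Path, stem: str = "volume") -> Path:
    """Write betas + mask as NIfTI and the metadata as a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_nifti(volume.betas, out_dir / f"{stem}_betas.nii.gz", volume.voxel_size_mm)
    save_nifti(
        volume.mask.astype(np.float64), out_dir / f"{stem}_mask.nii.gz",
        volume.voxel_size_mm,
    )
    manifest = {
        "format": "socialmvpa-volume",
        "version": __version__,
        "voxel_size_mm": volume.voxel_size_mm,
        "n_runs": volume.n_runs,
        "truth_centers": [list(c) for c in volume.truth_centers],
        "betas": f"{stem}_betas.nii.gz",
        "mask": f"{stem}_mask.nii.gz",
    }
    path = out_dir / f"{stem}_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def read_volume(manifest_path: str | Path) -> VolumeDataset:
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    betas, voxel_size = load_nifti(base / manifest["betas"])
    mask, _ = load_nifti(base / manifest["mask"])
    return VolumeDataset(
        betas=betas,
        mask=mask > 0.5,
        voxel_size_mm=manifest["voxel_size_mm"],
        n_runs=manifest["n_runs"],
        truth_centers=tuple(tuple(c) for c in manifest["truth_centers"]),
    )
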