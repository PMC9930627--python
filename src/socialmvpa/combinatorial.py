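"""Pairwise combinatorial-ROI joint decoding.

Each ROI's pattern is concatenated voxel-wise with every other ROI's
pattern and the decoding analysis is repeated on the combined pattern.
Comparing the joint accuracy with the row ROI's single-ROI baseline
quantifies how much accuracy an added ROI *contributes* to others (its
column of the delta matrix) versus how much it *benefits* from others (its
row) -- the "giver"/"taker" distinction between networks.

All joint patterns in one matrix share the same feature count, which the
analysis requires for fair comparison; unequal ROI sizes are refused
unless an explicit seeded voxel-subsampling equalization is requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import BetaPatterns
from .decoding import AccuracyResult, ClassifierSettings, DecodingScheme, decode
from .inference import TestResult, signed_rank_test


@dataclass(frozen=True)
class JointDeltaMatrix:
    """ROI x ROI change in accuracy (joint minus baseline of the row ROI).

    ``delta.loc[r, c]`` is the accuracy change for ROI *r* when ROI *c* is
    added to it; the diagonal is undefined (NaN).  The matrix is generally
    asymmetric because each row subtracts a different baseline.
    """

    delta: pd.DataFrame
    baseline: pd.Series
    scheme: str
    subject_id: str

    @property
    def roi_names(self) -> tuple[str, ...]:
        return tuple(self.delta.index)

    def averaged_pairs(self) -> pd.DataFrame:
        """Symmetric view averaging the two asymmetric deltas per pair."""
        sym = (self.delta + self.delta.T) / 2.0
        return sym


@dataclass(frozen=True)
class GiverTakerSummary:
    """Per-ROI contribution/benefit means and the DN-vs-SN network contrasts."""

    contribution: pd.Series
    benefit: pd.Series
    per_subject: pd.DataFrame
    contribution_contrast: TestResult | None
    benefit_contrast: TestResult | None
    networks: Mapping[str, str]


def _concatenate(patterns_a: BetaPatterns, patterns_b: BetaPatterns) -> np.ndarray:
    if patterns_a.subject_id != patterns_b.subject_id:
        raise ValueError("joint decoding requires patterns from the same subject")
    if patterns_a.values.shape[:2] != patterns_b.values.shape[:2]:
        raise ValueError("condition/run structure must match between ROIs")
    return np.concatenate([patterns_a.values, patterns_b.values], axis=2)


def joint_accuracy(
    patterns_a: BetaPatterns,
    patterns_b: BetaPatterns,
    scheme: DecodingScheme,
    settings: ClassifierSettings | None = None,
) -> AccuracyResult:
    """Decoding accuracy on the voxel-wise concatenation of two ROIs."""
    joint = _concatenate(patterns_a, patterns_b)
    result, _ = decode(joint, scheme, settings)
    return result


def _equalized(
    rois: Mapping[str, BetaPatterns], seed: int
) -> dict[str, BetaPatterns]:
    """Subsample every ROI (without replacement, seeded) to the minimum size."""
    target = min(p.n_voxels for p in rois.values())
    rng = np.random.default_rng(seed)
    out = {}
    for name in rois:
        p = rois[name]
        if p.n_voxels == target:
            out[name] = p
        else:
            keep = np.sort(rng.choice(p.n_voxels, size=target, replace=False))
            out[name] = BetaPatterns(
                values=p.values[:, :, keep], roi=p.roi, subject_id=p.subject_id
            )
    return out


def combinatorial_matrix(
    rois: Mapping[str, BetaPatterns],
    scheme: DecodingScheme,
    settings: ClassifierSettings | None = None,
    equalize_voxels: bool = False,
    seed: int = 0,
) -> JointDeltaMatrix:
    """Full pairwise joint-decoding delta matrix for one subject.

    With 8 ROIs this yields 56 defined off-diagonal deltas.  Baselines are
    computed once per ROI; the joint accuracy of an unordered pair is
    computed once and reused for both orientations (feature order is
    irrelevant to a linear kernel).
    """
    names = list(rois)
    if len(names) < 2:
        raise ValueError("need at least 2 ROIs")
    sizes = {p.n_voxels for p in rois.values()}
    if len(sizes) > 1:
        if not equalize_voxels:
            raise ValueError(
                "ROIs have unequal voxel counts; pass equalize_voxels=True "
                "to subsample (seeded)"
            )
        rois = _equalized(rois, seed)
    subject_id = next(iter(rois.values())).subject_id

    baseline = pd.Series(
        {name: decode(rois[name], scheme, settings)[0].accuracy for name in names},
        name="baseline",
    )
    delta = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            acc = joint_accuracy(rois[a], rois[b], scheme, settings).accuracy
            delta.loc[a, b] = acc - baseline[a]
            delta.loc[b, a] = acc - baseline[b]
    return JointDeltaMatrix(
        delta=delta, baseline=baseline, scheme=scheme.name, subject_id=subject_id
    )


def giver_taker_summary(
    matrices: Sequence[JointDeltaMatrix],
    networks: Mapping[str, str],
    alpha: float = 0.05,
) -> GiverTakerSummary:
    """Aggregate delta matrices over subjects into giver/taker measures.

    ``contribution`` of ROI *c* is the mean of its column (accuracy it adds
    to other ROIs); ``benefit`` of ROI *r* is the mean of its row (accuracy
    it gains from additions).  The DN-vs-SN contrasts are two-tailed
    signed-rank tests on subject-level network means.
    """
    if not matrices:
        raise ValueError("need at least one delta matrix")
    names = matrices[0].roi_names
    rows = []
    for m in matrices:
        contribution = m.delta.mean(axis=0, skipna=True)  # column means
        benefit = m.delta.mean(axis=1, skipna=True)       # row means
        for name in names:
            rows.append(
                {
                    "subject": m.subject_id,
                    "roi": name,
                    "network": networks.get(name, "control"),
                    "contribution": float(contribution[name]),
                    "benefit": float(benefit[name]),
                }
            )
    per_subject = pd.DataFrame(rows)

    group = per_subject.groupby("roi", sort=False)[["contribution", "benefit"]].mean()

    def contrast(measure: str) -> TestResult | None:
        by_net = per_subject.pivot_table(
            index="subject", columns="network", values=measure, aggfunc="mean"
        )
        if "DN" not in by_net.columns or "SN" not in by_net.columns:
            return None
        if len(by_net) < 2:
            raise ValueError("need >= 2 subjects for the network contrast")
        diffs = (by_net["DN"] - by_net["SN"]).to_numpy()
        return signed_rank_test(diffs, 0.0, tail="two")

    return GiverTakerSummary(
        contribution=group["contribution"],
        benefit=group["benefit"],
        per_subject=per_subject,
        contribution_contrast=contrast("contribution"),
        benefit_contrast=contrast("benefit"),
        networks=dict(networks),
    )
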