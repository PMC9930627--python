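"""Roaming-sphere (searchlight) decoding and group-level inference.

A sphere of fixed physical radius (default 10 mm) is centered on every
in-mask voxel; the multivoxel pattern of the sphere's in-mask voxels is
decoded with the same leave-one-run-out engine used for ROI decoding, and
the accuracy is assigned to the centroid voxel.  Group maps are tested
against chance with voxel-wise one-sample t tests, familywise error
controlled by a max-statistic sign-flipping permutation test (exact under
exchangeability of subject accuracy deviations around chance).

Also provides the localizer-style ROI definition: thresholding a t map at
a descending ladder of p levels, picking the suprathreshold local maximum
nearest a landmark coordinate, and returning a spherical mask around it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .cohort import VolumeDataset
from .decoding import ClassifierSettings, DecodingScheme, decode


class ROINotFoundError(RuntimeError):
    """No suprathreshold voxel at any ladder level near the landmark."""


@dataclass(frozen=True)
class AccuracyMap:
    """3-D accuracy grid (NaN outside the mask)."""

    values: np.ndarray
    mask: np.ndarray
    radius_mm: float
    scheme: str
    flagged: np.ndarray | None = None  # spheres with < 2 voxels

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        m = np.asarray(self.mask, dtype=bool)
        if v.shape != m.shape:
            raise ValueError("values and mask must share a grid")
        defined = v[m]
        if defined.size and (np.nanmin(defined) < 0 or np.nanmax(defined) > 1):
            raise ValueError("accuracies must lie in [0, 1]")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "mask", m)


@dataclass(frozen=True)
class GroupMap:
    """Voxel-wise group t map with a permutation-derived FWE threshold."""

    t_values: np.ndarray
    mask: np.ndarray
    threshold: float
    n_permutations: int
    chance: float
    significant: np.ndarray
    flagged: np.ndarray  # zero between-subject variance (t undefined)
    max_distribution: np.ndarray


@dataclass(frozen=True)
class ROIMask:
    center: tuple[int, int, int]
    radius_mm: float
    voxels: np.ndarray
    threshold_used: float
    t_critical: float


def sphere_offsets(radius_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Integer voxel offsets whose center-to-center distance is <= radius."""
    if radius_mm <= 0:
        raise ValueError("radius_mm must be > 0")
    r_vox = int(np.floor(radius_mm / voxel_size_mm))
    axis = np.arange(-r_vox, r_vox + 1)
    grid = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), axis=-1).reshape(-1, 3)
    dist = np.linalg.norm(grid * voxel_size_mm, axis=1)
    return grid[dist <= radius_mm + 1e-9]


def run_searchlight(
    volume: VolumeDataset,
    scheme: DecodingScheme,
    settings: ClassifierSettings | None = None,
    radius_mm: float = 10.0,
) -> AccuracyMap:
    """Decode the sphere neighborhood of every in-mask voxel.

    Out-of-mask voxels never enter any sphere.  Spheres containing fewer
    than 2 in-mask voxels still receive an accuracy but are flagged.
    """
    mask = volume.mask
    if not mask.any():
        raise ValueError("mask is empty")
    offsets = sphere_offsets(radius_mm, volume.voxel_size_mm)
    shape = np.asarray(volume.shape)
    values = np.full(volume.shape, np.nan)
    flagged = np.zeros(volume.shape, dtype=bool)
    centers = np.argwhere(mask)
    for center in centers:
        coords = center[None, :] + offsets
        inside = np.all((coords >= 0) & (coords < shape[None, :]), axis=1)
        coords = coords[inside]
        coords = coords[mask[coords[:, 0], coords[:, 1], coords[:, 2]]]
        patterns = volume.patterns_at(coords)
        result, _ = decode(patterns, scheme, settings)
        values[tuple(center)] = result.accuracy
        if len(coords) < 2:
            flagged[tuple(center)] = True
    return AccuracyMap(
        values=values,
        mask=mask,
        radius_mm=radius_mm,
        scheme=scheme.name,
        flagged=flagged,
    )


def group_searchlight_test(
    maps: list[AccuracyMap],
    chance: float,
    n_permutations: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> GroupMap:
    """Group inference: voxel-wise one-sample t vs chance, FWE by permutation.

    Familywise error is controlled by the sign-flipping max-statistic
    permutation distribution: per permutation each subject's accuracy
    deviation from chance is flipped with probability 1/2, t statistics are
    recomputed and the maximum over voxels recorded; the threshold is the
    (1 - alpha) quantile of that distribution.  Voxels with zero
    between-subject variance are flagged and excluded from the maximum.
    """
    if len(maps) < 2:
        raise ValueError("need >= 2 subjects")
    mask = maps[0].mask
    for m in maps:
        if m.mask.shape != mask.shape or not np.array_equal(m.mask, mask):
            raise ValueError("maps must share grid and mask")
    data = np.stack([m.values[mask] for m in maps])  # (S, V)
    n_subjects = data.shape[0]
    diffs = data - chance

    def t_stats(d: np.ndarray) -> np.ndarray:
        mean = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return mean / (sd / np.sqrt(n_subjects))

    sd0 = diffs.std(axis=0, ddof=1)
    degenerate = sd0 == 0
    t_obs = t_stats(diffs)
    t_obs[degenerate] = np.nan

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n_subjects))
    valid = ~degenerate
    max_dist = np.empty(n_permutations)
    d_valid = diffs[:, valid]
    ss = (d_valid ** 2).sum(axis=0)
    if d_valid.shape[1] == 0:
        max_dist[:] = np.inf  # no testable voxel: nothing can exceed threshold
    else:
        for p in range(n_permutations):
            m = signs[p] @ d_valid / n_subjects
            var = (ss - n_subjects * m ** 2) / (n_subjects - 1)
            with np.errstate(invalid="ignore", divide="ignore"):
                t_perm = m / np.sqrt(var / n_subjects)
            max_dist[p] = np.nanmax(t_perm)
    if np.isfinite(max_dist).all():
        threshold = float(np.quantile(max_dist, 1.0 - alpha))
    else:
        threshold = float("inf")

    t_grid = np.full(mask.shape, np.nan)
    t_grid[mask] = t_obs
    flagged_grid = np.zeros(mask.shape, dtype=bool)
    flagged_grid[mask] = degenerate
    significant = np.zeros(mask.shape, dtype=bool)
    sig_vals = np.zeros(mask.sum(), dtype=bool)
    sig_vals[valid] = t_obs[valid] > threshold
    significant[mask] = sig_vals
    return GroupMap(
        t_values=t_grid,
        mask=mask,
        threshold=threshold,
        n_permutations=n_permutations,
        chance=chance,
        significant=significant,
        flagged=flagged_grid,
        max_distribution=max_dist,
    )


def _local_maxima(t_map: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    """Voxels strictly greater than all 26-connected in-candidate neighbors.

    ``candidates`` restricts both the centers considered and the domain the
    neighbor values are drawn from (out-of-mask voxels are ignored).
    """
    footprint = np.ones((3, 3, 3), dtype=bool)
    padded = np.where(candidates, t_map, -np.inf)
    neighbor_max = ndimage.maximum_filter(
        padded, footprint=footprint, mode="constant", cval=-np.inf
    )
    # strictly greater than every neighbor: value equals the local max and
    # is attained uniquely; plateau ties resolved later by linear index
    is_max = candidates & (padded >= neighbor_max)
    return np.argwhere(is_max)


def define_roi_from_tmap(
    t_map: np.ndarray,
    landmark: tuple[int, int, int],
    df: int,
    radius_mm: float = 10.0,
    threshold_ladder: tuple[float, ...] = (0.001, 0.005, 0.01),
    voxel_size_mm: float = 3.0,
    mask: np.ndarray | None = None,
) -> ROIMask:
    """Define a spherical ROI from a t map near a landmark coordinate.

    The map is thresholded at the first ladder level (ascending p) that
    yields at least one suprathreshold in-mask voxel; among the local
    maxima of the suprathreshold set, the one nearest the landmark
    (Euclidean distance in millimeters, plateau ties broken by smallest
    linear index) becomes the sphere center.  Raises
    :class:`ROINotFoundError` if every ladder level is empty -- never a
    silent empty mask.
    """
    t_map = np.asarray(t_map, dtype=float)
    if mask is None:
        mask = np.ones(t_map.shape, dtype=bool)
    ladder = tuple(threshold_ladder)
    if not ladder or any(
        b <= a for a, b in zip(ladder, ladder[1:])
    ):
        raise ValueError("threshold ladder must be nonempty and increasing")
    landmark = tuple(int(c) for c in landmark)

    for p_level in ladder:
        t_crit = float(stats.t.ppf(1.0 - p_level, df))
        supra = mask & (t_map > t_crit)
        if not supra.any():
            continue
        maxima = _local_maxima(t_map, supra)
        if maxima.size == 0:
            continue
        dists = np.linalg.norm(
            (maxima - np.asarray(landmark)) * voxel_size_mm, axis=1
        )
        order = np.lexsort(
            (np.ravel_multi_index(maxima.T, t_map.shape), dists)
        )
        center = tuple(int(c) for c in maxima[order[0]])
        grid = np.indices(t_map.shape).reshape(3, -1).T
        dist_mm = np.linalg.norm((grid - center) * voxel_size_mm, axis=1)
        voxels = np.zeros(t_map.shape, dtype=bool)
        inside = grid[dist_mm <= radius_mm + 1e-9]
        voxels[inside[:, 0], inside[:, 1], inside[:, 2]] = True
        return ROIMask(
            center=center,
            radius_mm=radius_mm,
            voxels=voxels,
            threshold_used=p_level,
            t_critical=t_crit,
        )
    raise ROINotFoundError(
        f"no suprathreshold voxels near landmark {landmark} at any ladder "
        f"level {ladder}"
    )
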