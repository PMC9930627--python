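"""Synthetic cohort generation.

Generates condition-by-run beta patterns, pairwise behavioral similarity
ratings, and 4-D beta volumes with the statistical structure the downstream
analyses assume, so that every stage of the pipeline can be exercised and
calibrated without access to human data.

The generative model places the 8 conditions in a low-dimensional latent
space with three orthogonal axes:

* a bipartite **self/other** axis separating {PresentSelf, PastSelf} from
  {Mother, Queen} by ``d_self_other``;
* a **near/far social-distance** axis nested within each domain (PresentSelf
  and Mother are the "near" members, PastSelf and Queen the "far" members),
  with within-domain separation ``d_distance``;
* a **valence** axis separating the positive and negative variant of each
  person by ``d_valence``.

Each ROI embeds the latent means into voxel space through a random matrix
with orthonormal columns (so the separation structure is preserved and the
information content is governed by ``info_scale`` alone), then adds Gaussian
noise at two levels: a run-level offset shared by all conditions within a
run, and independent voxel-level noise per beta estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .labels import CONDITIONS, N_CONDITIONS, ConditionLabel, Person, Valence


class ConfigurationError(ValueError):
    """Raised when generative parameters are inconsistent."""


# --------------------------------------------------------------------------- #
# Parameter containers
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class GeometryParams:
    """Latent geometry of the 8 condition means.

    Setting every separation to zero defines the null (signal-free)
    geometry used for chance-level calibration.  ``subject_jitter_sd``
    is the SD of the Gaussian perturbation applied to a subject's
    condition means; when ``None`` it defaults to 10% of ``d_self_other``
    (hence exactly zero in the null geometry).
    """

    d_self_other: float = 2.0
    d_distance: float = 1.0
    d_valence: float = 0.3
    latent_dim: int = 6
    seed: int = 0
    subject_jitter_sd: float | None = None

    def __post_init__(self) -> None:
        for name in ("d_self_other", "d_distance", "d_valence"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.latent_dim < 2:
            raise ConfigurationError("latent_dim must be >= 2")
        n_axes = sum(
            d > 0 for d in (self.d_self_other, self.d_distance, self.d_valence)
        )
        if self.latent_dim < n_axes:
            raise ConfigurationError(
                "latent_dim too small to embed the requested separations"
            )
        if self.subject_jitter_sd is not None and self.subject_jitter_sd < 0:
            raise ConfigurationError("subject_jitter_sd must be >= 0")

    @property
    def effective_jitter_sd(self) -> float:
        if self.subject_jitter_sd is not None:
            return self.subject_jitter_sd
        return 0.1 * self.d_self_other

    def to_dict(self) -> dict:
        return {
            "d_self_other": self.d_self_other,
            "d_distance": self.d_distance,
            "d_valence": self.d_valence,
            "latent_dim": self.latent_dim,
            "seed": self.seed,
            "subject_jitter_sd": self.subject_jitter_sd,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeometryParams":
        return cls(**dict(d))


NULL_GEOMETRY = GeometryParams(
    d_self_other=0.0, d_distance=0.0, d_valence=0.0, subject_jitter_sd=0.0
)


@dataclass(frozen=True)
class ROISpec:
    """Generative description of one region of interest."""

    name: str
    network: str  # "DN" | "SN" | "control"
    n_voxels: int = 80
    info_scale: float = 1.0
    noise_sd_run: float = 0.3
    noise_sd_voxel: float = 0.6

    def __post_init__(self) -> None:
        if self.network not in ("DN", "SN", "control"):
            raise ConfigurationError(f"unknown network {self.network!r}")
        if self.n_voxels <= 0:
            raise ConfigurationError("n_voxels must be positive")
        if self.info_scale < 0:
            raise ConfigurationError("info_scale must be >= 0")
        if self.noise_sd_run < 0 or self.noise_sd_voxel < 0:
            raise ConfigurationError("noise SDs must be >= 0")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "network": self.network,
            "n_voxels": self.n_voxels,
            "info_scale": self.info_scale,
            "noise_sd_run": self.noise_sd_run,
            "noise_sd_voxel": self.noise_sd_voxel,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ROISpec":
        return cls(**dict(d))


def default_rois(
    dn_info_scale: float = 1.0,
    sn_info_scale: float = 0.45,
    n_voxels: int = 80,
) -> tuple[ROISpec, ...]:
    """The study's 8 ROIs: 5 default-network, 3 semantic-network regions.

    DN regions are assigned a higher information scale than SN regions,
    mirroring the planted asymmetry the analyses are meant to recover.
    """
    dn = ("dmPFC", "vmPFC", "PCC", "lIPL", "rIPL")
    sn = ("lATL", "rATL", "lIFG")
    return tuple(
        [ROISpec(name, "DN", n_voxels, dn_info_scale) for name in dn]
        + [ROISpec(name, "SN", n_voxels, sn_info_scale) for name in sn]
    )


@dataclass(frozen=True)
class CohortSpec:
    """Full specification of a synthetic cohort."""

    n_subjects: int = 24
    n_runs: int = 8
    rois: tuple[ROISpec, ...] = field(default_factory=default_rois)
    geometry: GeometryParams = field(default_factory=GeometryParams)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be positive")
        if self.n_runs < 2:
            raise ConfigurationError("n_runs must be >= 2")
        if len({r.name for r in self.rois}) != len(self.rois):
            raise ConfigurationError("ROI names must be unique")
        object.__setattr__(self, "rois", tuple(self.rois))

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(f"sub-{i + 1:02d}" for i in range(self.n_subjects))

    @property
    def roi_names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.rois)

    def roi(self, name: str) -> ROISpec:
        for r in self.rois:
            if r.name == name:
                return r
        raise KeyError(name)

    def networks(self) -> dict[str, str]:
        return {r.name: r.network for r in self.rois}

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "n_runs": self.n_runs,
            "rois": [r.to_dict() for r in self.rois],
            "geometry": self.geometry.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSpec":
        return cls(
            n_subjects=d["n_subjects"],
            n_runs=d["n_runs"],
            rois=tuple(ROISpec.from_dict(r) for r in d["rois"]),
            geometry=GeometryParams.from_dict(d["geometry"]),
        )


# --------------------------------------------------------------------------- #
# Data containers
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class BetaPatterns:
    """Per subject/ROI array of beta vectors indexed by (condition, run).

    ``values`` has shape ``(8, n_runs, n_voxels)`` with conditions in the
    canonical person-major order of :data:`socialmvpa.labels.CONDITIONS`.
    With 8 runs this holds the study's 64 beta vectors per ROI.
    """

    values: np.ndarray
    roi: ROISpec
    subject_id: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[0] != N_CONDITIONS:
            raise ValueError(
                "values must have shape (8, n_runs, n_voxels); "
                f"got {v.shape}"
            )
        object.__setattr__(self, "values", v)

    @property
    def n_runs(self) -> int:
        return self.values.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[2]

    def vector(self, condition: ConditionLabel, run: int) -> np.ndarray:
        return self.values[condition.index, run]


@dataclass(frozen=True)
class Cohort:
    """Collection of BetaPatterns over subjects x ROIs."""

    spec: CohortSpec
    patterns: Mapping[tuple[str, str], BetaPatterns]

    def get(self, subject_id: str, roi_name: str) -> BetaPatterns:
        return self.patterns[(subject_id, roi_name)]

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return self.spec.subject_ids

    @property
    def roi_names(self) -> tuple[str, ...]:
        return self.spec.roi_names

    def subject_rois(self, subject_id: str) -> dict[str, BetaPatterns]:
        return {name: self.get(subject_id, name) for name in self.roi_names}


@dataclass(frozen=True)
class RatingMatrix:
    """Pairwise person-similarity ratings on the 0-100 scale (symmetric 4x4)."""

    values: np.ndarray
    subject_id: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (4, 4):
            raise ValueError("rating matrix must be 4x4")
        if not np.allclose(v, v.T):
            raise ValueError("rating matrix must be symmetric")
        if np.nanmin(v) < 0 or np.nanmax(v) > 100:
            raise ValueError("ratings must lie in [0, 100]")
        object.__setattr__(self, "values", v)

    def rating(self, a: Person, b: Person) -> float:
        return float(self.values[int(a), int(b)])


#: Unordered person pairs in canonical order (6 pairs).
PERSON_PAIRS: tuple[tuple[Person, Person], ...] = tuple(
    (Person(i), Person(j)) for i in range(4) for j in range(i + 1, 4)
)

#: Default pairwise similarity-rating means, encoding the qualitative
#: behavioral pattern: Mother rated nearly as similar to the present self as
#: (indeed slightly more than) the past self, and the Queen rated distant
#: from everyone familiar.
DEFAULT_RATING_MEANS: dict[tuple[Person, Person], float] = {
    (Person.PRESENT_SELF, Person.PAST_SELF): 65.0,
    (Person.PRESENT_SELF, Person.MOTHER): 72.0,
    (Person.PRESENT_SELF, Person.QUEEN): 15.0,
    (Person.PAST_SELF, Person.MOTHER): 60.0,
    (Person.PAST_SELF, Person.QUEEN): 20.0,
    (Person.MOTHER, Person.QUEEN): 25.0,
}


@dataclass(frozen=True)
class VolumeDataset:
    """4-D beta volume plus mask for searchlight analysis.

    ``betas`` has shape ``(nx, ny, nz, 8 * n_runs)``; the 4th axis is
    condition-major (feature index = condition_index * n_runs + run).
    Grid indices are 0-based and physical coordinates are
    ``index * voxel_size_mm`` (identity affine scaled by voxel size).
    """

    betas: np.ndarray
    mask: np.ndarray
    voxel_size_mm: float
    n_runs: int
    truth_centers: tuple[tuple[int, int, int], ...] = ()

    def __post_init__(self) -> None:
        b = np.asarray(self.betas, dtype=float)
        m = np.asarray(self.mask, dtype=bool)
        if b.ndim != 4 or b.shape[:3] != m.shape:
            raise ValueError("betas must be 4-D and aligned with the 3-D mask")
        if b.shape[3] != N_CONDITIONS * self.n_runs:
            raise ValueError("4th axis must hold 8 * n_runs beta volumes")
        object.__setattr__(self, "betas", b)
        object.__setattr__(self, "mask", m)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.betas.shape[:3]

    def patterns_at(self, coords: np.ndarray) -> np.ndarray:
        """Extract (8, n_runs, n_voxels) beta patterns at voxel coordinates."""
        coords = np.asarray(coords)
        flat = self.betas[coords[:, 0], coords[:, 1], coords[:, 2], :]
        # (k, 8*n_runs) -> (8, n_runs, k)
        return flat.reshape(len(coords), N_CONDITIONS, self.n_runs).transpose(1, 2, 0)


# --------------------------------------------------------------------------- #
# Generators
# --------------------------------------------------------------------------- #


def build_geometry(params: GeometryParams) -> np.ndarray:
    """Latent mean vectors for the 8 conditions, shape (8, latent_dim).

    Axes are assigned in the fixed order self/other -> distance -> valence,
    skipping axes whose separation is zero; the construction is fully
    deterministic (the seed in ``params`` only governs downstream sampling).
    """
    means = np.zeros((N_CONDITIONS, params.latent_dim))
    axis = 0
    if params.d_self_other > 0:
        for cond in CONDITIONS:
            sign = -1.0 if cond.person.domain == "self" else 1.0
            means[cond.index, axis] = sign * params.d_self_other / 2.0
        axis += 1
    if params.d_distance > 0:
        for cond in CONDITIONS:
            sign = -1.0 if cond.person.distance == "near" else 1.0
            means[cond.index, axis] = sign * params.d_distance / 2.0
        axis += 1
    if params.d_valence > 0:
        for cond in CONDITIONS:
            sign = -1.0 if cond.valence is Valence.POSITIVE else 1.0
            means[cond.index, axis] = sign * params.d_valence / 2.0
    return means


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_roi_patterns(
    geometry: np.ndarray,
    roi: ROISpec,
    n_runs: int,
    seed: int | np.random.Generator,
    subject_id: str = "sub-01",
) -> BetaPatterns:
    """Simulate condition-by-run beta vectors for one ROI.

    Each (condition, run) vector is a random orthonormal embedding of the
    condition's latent mean into voxel space, scaled by ``roi.info_scale``,
    plus run-level and voxel-level Gaussian noise.  Bit-identical for a
    given seed.
    """
    if n_runs < 2:
        raise ConfigurationError("n_runs must be >= 2")
    geometry = np.asarray(geometry, dtype=float)
    latent_dim = geometry.shape[1]
    if roi.n_voxels < latent_dim:
        raise ConfigurationError(
            f"ROI {roi.name!r} has fewer voxels ({roi.n_voxels}) than "
            f"latent dimensions ({latent_dim})"
        )
    rng = _as_rng(seed)
    # Random loading matrix with orthonormal columns: preserves latent
    # separations so information is controlled by info_scale alone.
    loading, _ = np.linalg.qr(rng.standard_normal((roi.n_voxels, latent_dim)))
    signal = roi.info_scale * geometry @ loading.T  # (8, n_voxels)
    run_noise = roi.noise_sd_run * rng.standard_normal((n_runs, roi.n_voxels))
    voxel_noise = roi.noise_sd_voxel * rng.standard_normal(
        (N_CONDITIONS, n_runs, roi.n_voxels)
    )
    values = signal[:, None, :] + run_noise[None, :, :] + voxel_noise
    return BetaPatterns(values=values, roi=roi, subject_id=subject_id)


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate the full cohort: subjects x ROIs of beta patterns.

    Every subject shares the configured latent geometry but receives a
    small Gaussian jitter on the condition means (individual
    representational idiosyncrasy), so that between-subject noise-ceiling
    bounds are nondegenerate.  Fully reproducible from
    ``spec.geometry.seed``.
    """
    base = build_geometry(spec.geometry)
    jitter_sd = spec.geometry.effective_jitter_sd
    master = np.random.SeedSequence(spec.geometry.seed)
    subj_seqs = master.spawn(spec.n_subjects)
    patterns: dict[tuple[str, str], BetaPatterns] = {}
    for subject_id, seq in zip(spec.subject_ids, subj_seqs):
        streams = seq.spawn(len(spec.rois) + 1)
        jitter_rng = np.random.default_rng(streams[0])
        means = base + jitter_sd * jitter_rng.standard_normal(base.shape)
        for roi, stream in zip(spec.rois, streams[1:]):
            rng = np.random.default_rng(stream)
            patterns[(subject_id, roi.name)] = simulate_roi_patterns(
                means, roi, spec.n_runs, rng, subject_id=subject_id
            )
    return Cohort(spec=spec, patterns=patterns)


def simulate_behavioral_ratings(
    spec: CohortSpec,
    rating_means: Mapping[tuple[Person, Person], float] | None = None,
    rating_sd: float = 8.0,
    seed: int | np.random.Generator = 0,
) -> dict[str, RatingMatrix]:
    """Per-subject pairwise similarity ratings on the 0-100 scale.

    Ratings are Gaussian around the configured pair means and clipped to
    [0, 100]; with ``rating_sd = 0`` they equal the means exactly.
    """
    if rating_sd < 0:
        raise ConfigurationError("rating_sd must be >= 0")
    means = dict(DEFAULT_RATING_MEANS if rating_means is None else rating_means)
    for pair, m in means.items():
        if not 0 <= m <= 100:
            raise ConfigurationError(f"rating mean for {pair} outside [0, 100]")
    rng = _as_rng(seed)
    out: dict[str, RatingMatrix] = {}
    for subject_id in spec.subject_ids:
        mat = np.full((4, 4), 100.0)
        for (a, b) in PERSON_PAIRS:
            val = means[(a, b)] + rating_sd * rng.standard_normal()
            val = float(np.clip(val, 0.0, 100.0))
            mat[int(a), int(b)] = mat[int(b), int(a)] = val
        out[subject_id] = RatingMatrix(values=mat, subject_id=subject_id)
    return out


def simulate_brain_volume(
    shape: tuple[int, int, int] = (12, 12, 12),
    voxel_size_mm: float = 3.0,
    mask: np.ndarray | None = None,
    sphere_centers: Sequence[tuple[int, int, int]] = (),
    sphere_radius_mm: float = 6.0,
    geometry: GeometryParams | None = None,
    info_scale: float = 1.0,
    n_runs: int = 8,
    noise_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> VolumeDataset:
    """Simulate a 4-D beta volume with optional planted informative spheres.

    Voxels inside the planted spheres carry condition signal generated from
    ``geometry`` (each voxel gets its own random latent loading); all other
    in-mask voxels are pure noise.  Out-of-mask voxels carry no planted
    signal.
    """
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != tuple(shape):
        raise ConfigurationError("mask shape must match the grid shape")
    geometry = geometry if geometry is not None else GeometryParams()
    means = build_geometry(geometry)  # (8, latent_dim)
    rng = _as_rng(seed)

    betas = noise_sd * rng.standard_normal(tuple(shape) + (N_CONDITIONS * n_runs,))

    grid = np.indices(shape).reshape(3, -1).T  # all voxel coords
    for center in sphere_centers:
        center = tuple(int(c) for c in center)
        if any(c < 0 or c >= s for c, s in zip(center, shape)):
            raise ConfigurationError(f"sphere center {center} outside the grid")
        if not mask[center]:
            raise ConfigurationError(f"sphere center {center} outside the mask")
        dist_mm = np.linalg.norm((grid - center) * voxel_size_mm, axis=1)
        inside = grid[dist_mm <= sphere_radius_mm]
        for (x, y, z) in inside:
            if not mask[x, y, z]:
                continue  # planted signal never leaks outside the mask
            w = rng.standard_normal(means.shape[1]) / np.sqrt(means.shape[1])
            sig = info_scale * means @ w  # (8,)
            betas[x, y, z, :] += np.repeat(sig, n_runs)

    return VolumeDataset(
        betas=betas,
        mask=mask,
        voxel_size_mm=float(voxel_size_mm),
        n_runs=n_runs,
        truth_centers=tuple(tuple(int(c) for c in ctr) for ctr in sphere_centers),
    )
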