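"""Representational similarity analysis.

First-order analysis computes condition-by-condition Pearson similarity
matrices from run-averaged beta patterns.  Second-order analyses compare
such matrices -- across valence contexts, across subjects (noise
ceilings), across regions, and against theoretical model RDMs -- using the
rank correlations standard in RSA: Kendall's tau-a (no tie correction) and
Spearman's rho, always over the off-diagonal lower triangle only.

Similarity (r) and distance (1 - r) are two views of the same matrix;
hierarchical clustering and model comparison operate on the distance view.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .cohort import BetaPatterns, Cohort, RatingMatrix
from .decoding import ClassifierSettings, DecodingScheme, cross_validate
from .inference import AnovaResult, rm_anova_2x2, signed_rank_test
from .labels import CONDITIONS, Person, Valence

EIGHT_CONDITION = "eight_condition"
FOUR_PERSON = "four_person"

RANK_METHODS = ("kendall_tau_a", "spearman_rho")


# --------------------------------------------------------------------------- #
# First-order similarity
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class SimilarityMatrix:
    """Condition x condition Pearson similarity with a 1 - r distance view."""

    values: np.ndarray
    labels: tuple[str, ...]
    level: str
    flagged: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("values must be square and aligned with labels")
        object.__setattr__(self, "values", v)

    @property
    def distance(self) -> np.ndarray:
        return 1.0 - self.values

    @property
    def lower_triangle(self) -> np.ndarray:
        """The m(m-1)/2 off-diagonal lower-triangular entries (row-major)."""
        i, j = np.tril_indices(len(self.labels), k=-1)
        return self.values[i, j]

    @property
    def distance_lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(len(self.labels), k=-1)
        return self.distance[i, j]


def _pearson_matrix(patterns: np.ndarray) -> tuple[np.ndarray, bool]:
    flagged = bool(np.any(patterns.std(axis=1) == 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(patterns)
    return r, flagged or bool(np.isnan(r).any())


def condition_rdm(
    patterns: BetaPatterns,
    level: str = EIGHT_CONDITION,
    valence: Valence | None = None,
    run_average: bool = True,
) -> SimilarityMatrix:
    """Pearson similarity between condition patterns.

    Condition patterns are the run-averaged beta vectors per condition (the
    default); with ``run_average=False`` a similarity matrix is computed per
    run and the matrices are Fisher-z averaged.  ``four_person`` level
    averages the two valence variants of each person first; passing
    ``valence`` restricts to one valence context (always person-level).
    """
    values = patterns.values  # (8, n_runs, V)
    if valence is not None:
        conds = [c for c in CONDITIONS if c.valence is valence]
        labels = tuple(c.person.label for c in conds)
        idx_groups = [[c.index] for c in conds]
        level = FOUR_PERSON
    elif level == EIGHT_CONDITION:
        labels = tuple(c.label for c in CONDITIONS)
        idx_groups = [[c.index] for c in CONDITIONS]
    elif level == FOUR_PERSON:
        labels = tuple(p.label for p in Person)
        idx_groups = [
            [c.index for c in CONDITIONS if c.person is p] for p in Person
        ]
    else:
        raise ValueError(f"unknown level {level!r}")

    if values.shape[2] < 2:
        raise ValueError("need >= 2 voxels for pattern correlations")

    if run_average:
        mats = [values[:, :, :].mean(axis=1)]  # (8, V)
    else:
        mats = [values[:, r, :] for r in range(values.shape[1])]

    sims, any_flag = [], False
    for mat in mats:
        grouped = np.stack([mat[idx].mean(axis=0) for idx in idx_groups])
        r, flagged = _pearson_matrix(grouped)
        any_flag |= flagged
        sims.append(r)
    if len(sims) == 1:
        r = sims[0]
    else:
        z = np.arctanh(np.clip(np.stack(sims), -0.999999, 0.999999))
        r = np.tanh(z.mean(axis=0))
        np.fill_diagonal(r, 1.0)
    return SimilarityMatrix(values=r, labels=labels, level=level, flagged=any_flag)


def average_similarity(matrices: Sequence[SimilarityMatrix]) -> SimilarityMatrix:
    """Entrywise average of similarity matrices (same labels required)."""
    labels = matrices[0].labels
    for m in matrices:
        if m.labels != labels:
            raise ValueError("matrices must share labels")
    values = np.mean([m.values for m in matrices], axis=0)
    return SimilarityMatrix(
        values=values,
        labels=labels,
        level=matrices[0].level,
        flagged=any(m.flagged for m in matrices),
    )


# --------------------------------------------------------------------------- #
# Rank correlations
# --------------------------------------------------------------------------- #


def kendall_tau_a(x, y) -> float:
    """Kendall's tau-a: (concordant - discordant) / (n(n-1)/2), no tie term."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    i, j = np.triu_indices(x.size, k=1)
    s = dx[i, j] * dy[i, j]
    return float(s.sum() / (x.size * (x.size - 1) / 2))


def rank_correlation(x, y, method: str = "kendall_tau_a") -> float:
    """Rank correlation between two vectors; NaN if either is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    if method == "kendall_tau_a":
        return kendall_tau_a(x, y)
    if method == "spearman_rho":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


# --------------------------------------------------------------------------- #
# Cross-valence consistency
# --------------------------------------------------------------------------- #


def cross_valence_consistency(
    cohort: Cohort,
    method: str = "kendall_tau_a",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Consistency of the person-level representational geometry across valence.

    For each subject and ROI, a 4x4 person similarity matrix is built
    separately from the positive and the negative conditions, their lower
    triangles are rank-correlated, and the per-subject coefficients are
    tested against zero per ROI with a one-tailed signed-rank test
    (Bonferroni over ROIs).  Returns ``(group_table, per_subject)``.
    """
    rows = []
    for subject_id in cohort.subject_ids:
        for roi_name in cohort.roi_names:
            patterns = cohort.get(subject_id, roi_name)
            pos = condition_rdm(patterns, valence=Valence.POSITIVE)
            neg = condition_rdm(patterns, valence=Valence.NEGATIVE)
            coef = rank_correlation(
                pos.lower_triangle, neg.lower_triangle, method
            )
            rows.append(
                {"subject": subject_id, "roi": roi_name, "coefficient": coef}
            )
    per_subject = pd.DataFrame(rows)

    n_rois = len(cohort.roi_names)
    group_rows = []
    for roi_name in cohort.roi_names:
        coefs = per_subject.loc[
            per_subject["roi"] == roi_name, "coefficient"
        ].to_numpy()
        coefs = coefs[~np.isnan(coefs)]
        test = signed_rank_test(coefs, 0.0, tail="one").with_bonferroni(
            n_rois, alpha
        )
        group_rows.append(
            {
                "roi": roi_name,
                "mean_coefficient": float(np.mean(coefs)),
                "statistic": test.statistic,
                "p": test.p,
                "alpha_corrected": test.alpha_corrected,
                "significant": test.significant_bonferroni,
            }
        )
    return pd.DataFrame(group_rows), per_subject


# --------------------------------------------------------------------------- #
# Noise ceiling
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class NoiseCeiling:
    """Bracket on the best correlation a true model could achieve.

    ``upper`` is the mean correlation of each subject's matrix with the
    group mean including that subject; ``lower`` is the leave-one-subject-out
    version.
    """

    lower: float
    upper: float


def noise_ceiling(
    matrices: Sequence[SimilarityMatrix],
    method: str = "kendall_tau_a",
) -> NoiseCeiling:
    if len(matrices) < 3:
        raise ValueError("need >= 3 subjects")
    vectors = np.stack([m.lower_triangle for m in matrices])
    n = len(vectors)
    total = vectors.sum(axis=0)
    upper_vals, lower_vals = [], []
    for i in range(n):
        upper_vals.append(rank_correlation(vectors[i], total / n, method))
        loo = (total - vectors[i]) / (n - 1)
        lower_vals.append(rank_correlation(vectors[i], loo, method))
    return NoiseCeiling(
        lower=float(np.nanmean(lower_vals)), upper=float(np.nanmean(upper_vals))
    )


# --------------------------------------------------------------------------- #
# Hierarchical clustering
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class DendrogramTree:
    """Agglomerative clustering result with labeled merge bookkeeping."""

    linkage_matrix: np.ndarray
    labels: tuple[str, ...]
    method: str

    @property
    def merges(self) -> tuple[tuple[tuple[str, ...], tuple[str, ...], float], ...]:
        """Ordered merge sequence as (members_a, members_b, height)."""
        n = len(self.labels)
        clusters: dict[int, tuple[str, ...]] = {
            i: (self.labels[i],) for i in range(n)
        }
        out = []
        for k, (a, b, height, _) in enumerate(self.linkage_matrix):
            ca, cb = clusters[int(a)], clusters[int(b)]
            out.append((ca, cb, float(height)))
            clusters[n + k] = ca + cb
        return tuple(out)

    def first_split(self) -> tuple[frozenset, frozenset]:
        """The two clusters joined by the final (root) merge."""
        a, b, _ = self.merges[-1]
        return frozenset(a), frozenset(b)

    def to_newick(self) -> str:
        n = len(self.labels)
        nodes: dict[int, str] = {i: self.labels[i] for i in range(n)}
        heights: dict[int, float] = {i: 0.0 for i in range(n)}
        for k, (a, b, height, _) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            la = height - heights[a]
            lb = height - heights[b]
            nodes[n + k] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
            heights[n + k] = height
        return nodes[n + len(self.linkage_matrix) - 1] + ";"

    def merge_table(self) -> pd.DataFrame:
        rows = [
            {
                "step": k,
                "cluster_a": "+".join(a),
                "cluster_b": "+".join(b),
                "height": h,
            }
            for k, (a, b, h) in enumerate(self.merges)
        ]
        return pd.DataFrame(rows)


def hierarchical_clustering(
    distance_matrix: np.ndarray,
    labels: Sequence[str] | None = None,
    linkage: str = "average",
) -> DendrogramTree:
    """Agglomerative clustering of a square distance matrix (UPGMA default)."""
    d = np.asarray(distance_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    if d.min() < -1e-12:
        raise ValueError("distances must be nonnegative")
    labels = tuple(labels) if labels is not None else tuple(
        str(i) for i in range(d.shape[0])
    )
    condensed = squareform(np.clip(d, 0, None), checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    return DendrogramTree(linkage_matrix=Z, labels=labels, method=linkage)


# --------------------------------------------------------------------------- #
# Model RDMs and model comparison
# --------------------------------------------------------------------------- #


PERSON_LABELS = tuple(p.label for p in Person)


@dataclass(frozen=True)
class ModelRDM:
    """Theoretical 4-person dissimilarity matrix."""

    kind: str
    values: np.ndarray
    flagged: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (4, 4):
            raise ValueError("model RDM must be 4x4")
        object.__setattr__(self, "values", v)

    @property
    def lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(4, k=-1)
        return self.values[i, j]


def model_rdm(kind: str, ratings: RatingMatrix | None = None) -> ModelRDM:
    """Construct a theoretical model RDM.

    * ``binary`` -- 0 within the self pair and within the other pair,
      1 between domains;
    * ``graded`` -- |position_i - position_j| on the equidistant
      social-distance spectrum (positions 0..3);
    * ``behavioral`` -- (100 - rating) / 100 from a subject's pairwise
      similarity ratings (flagged degenerate if the ratings are constant).
    """
    values = np.zeros((4, 4))
    if kind == "binary":
        for a in Person:
            for b in Person:
                values[a, b] = 0.0 if a.domain == b.domain else 1.0
    elif kind == "graded":
        for a in Person:
            for b in Person:
                values[a, b] = abs(int(a) - int(b))
    elif kind == "behavioral":
        if ratings is None:
            raise ValueError("behavioral model requires a RatingMatrix")
        values = (100.0 - ratings.values) / 100.0
        np.fill_diagonal(values, 0.0)
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    i, j = np.tril_indices(4, k=-1)
    flagged = bool(np.all(values[i, j] == values[i, j][0]))
    return ModelRDM(kind=kind, values=values, flagged=flagged)


@dataclass(frozen=True)
class ModelComparisonResult:
    table: pd.DataFrame
    contrasts: pd.DataFrame
    noise_ceilings: pd.DataFrame
    per_subject: pd.DataFrame
    excluded_models: tuple[str, ...] = ()


def model_comparison(
    neural: Mapping[str, Sequence[SimilarityMatrix]],
    models: Mapping[str, "ModelRDM | Mapping[str, ModelRDM]"],
    subject_ids: Sequence[str],
    method: str = "kendall_tau_a",
    alpha: float = 0.05,
) -> ModelComparisonResult:
    """Compare theoretical model RDMs against neural similarity matrices.

    ``neural`` maps each ROI to its per-subject person-level (4x4)
    similarity matrices, aligned with ``subject_ids``.  Each entry of
    ``models`` is either one ModelRDM shared by all subjects or a mapping
    of subject id to a subject-specific ModelRDM (behavioral ratings).

    Neural matrices are converted to the 1 - r distance view so that a
    positive rank correlation means the model predicts the neural
    geometry.  Per ROI and model, per-subject coefficients are tested
    against zero (one-tailed signed-rank, Bonferroni over ROIs); model
    pairs are contrasted with two-tailed signed-rank tests on the
    per-subject coefficient differences, both per ROI and on the
    across-ROI subject means.  Degenerate (flat) models are excluded with
    a warning flag in ``excluded_models``.
    """
    roi_names = list(neural)
    n_rois = len(roi_names)

    def subject_model(name: str, subject_id: str) -> ModelRDM:
        entry = models[name]
        if isinstance(entry, ModelRDM):
            return entry
        return entry[subject_id]

    excluded = []
    for name in models:
        entry = models[name]
        rdms = [entry] if isinstance(entry, ModelRDM) else list(entry.values())
        if all(r.flagged for r in rdms):
            excluded.append(name)
    kept = [name for name in models if name not in excluded]

    rows = []
    for roi_name in roi_names:
        mats = neural[roi_name]
        if len(mats) != len(subject_ids):
            raise ValueError("per-ROI matrices must align with subject_ids")
        for model_name in kept:
            for subject_id, mat in zip(subject_ids, mats):
                rdm = subject_model(model_name, subject_id)
                coef = rank_correlation(
                    mat.distance_lower_triangle, rdm.lower_triangle, method
                )
                rows.append(
                    {
                        "roi": roi_name,
                        "model": model_name,
                        "subject": subject_id,
                        "coefficient": coef,
                    }
                )
    per_subject = pd.DataFrame(rows)

    table_rows = []
    for roi_name in roi_names:
        for model_name in kept:
            coefs = per_subject.query(
                "roi == @roi_name and model == @model_name"
            )["coefficient"].to_numpy()
            coefs = coefs[~np.isnan(coefs)]
            test = signed_rank_test(coefs, 0.0, tail="one").with_bonferroni(
                n_rois, alpha
            )
            table_rows.append(
                {
                    "roi": roi_name,
                    "model": model_name,
                    "mean_coefficient": float(np.mean(coefs)),
                    "statistic": test.statistic,
                    "p": test.p,
                    "alpha_corrected": test.alpha_corrected,
                    "significant": test.significant_bonferroni,
                }
            )
    table = pd.DataFrame(table_rows)

    contrast_rows = []
    wide = per_subject.pivot_table(
        index=["roi", "subject"], columns="model", values="coefficient"
    )
    for model_a, model_b in combinations(kept, 2):
        for roi_name in roi_names:
            sub = wide.loc[roi_name]
            diffs = (sub[model_a] - sub[model_b]).dropna().to_numpy()
            test = signed_rank_test(diffs, 0.0, tail="two")
            contrast_rows.append(
                {
                    "roi": roi_name,
                    "model_a": model_a,
                    "model_b": model_b,
                    "statistic": test.statistic,
                    "p": test.p,
                }
            )
        # across-ROI contrast on the per-subject means
        means = wide.groupby("subject")[[model_a, model_b]].mean()
        diffs = (means[model_a] - means[model_b]).dropna().to_numpy()
        test = signed_rank_test(diffs, 0.0, tail="two")
        contrast_rows.append(
            {
                "roi": "all",
                "model_a": model_a,
                "model_b": model_b,
                "statistic": test.statistic,
                "p": test.p,
            }
        )
    contrasts = pd.DataFrame(contrast_rows)

    ceiling_rows = []
    for roi_name in roi_names:
        ceiling = noise_ceiling(list(neural[roi_name]), method)
        ceiling_rows.append(
            {"roi": roi_name, "lower": ceiling.lower, "upper": ceiling.upper}
        )
    ceilings = pd.DataFrame(ceiling_rows)
    ceilings = pd.concat(
        [
            ceilings,
            pd.DataFrame(
                [
                    {
                        "roi": "mean",
                        "lower": ceilings["lower"].mean(),
                        "upper": ceilings["upper"].mean(),
                    }
                ]
            ),
        ],
        ignore_index=True,
    )

    return ModelComparisonResult(
        table=table,
        contrasts=contrasts,
        noise_ceilings=ceilings,
        per_subject=per_subject,
        excluded_models=tuple(excluded),
    )


# --------------------------------------------------------------------------- #
# Second-order region analyses
# --------------------------------------------------------------------------- #


def second_order_region_similarity(
    matrices: Mapping[str, "SimilarityMatrix | Sequence[SimilarityMatrix]"],
    method: str = "kendall_tau_a",
    linkage: str = "average",
) -> tuple[pd.DataFrame, DendrogramTree]:
    """Region x region similarity of representational geometries.

    Rank-correlates the lower triangles of every pair of region-level
    (group-averaged) eight-condition similarity matrices, then clusters
    the resulting 1 - coefficient distances.
    """
    if len(matrices) < 2:
        raise ValueError("need >= 2 regions")
    averaged: dict[str, SimilarityMatrix] = {}
    for name, entry in matrices.items():
        if isinstance(entry, SimilarityMatrix):
            averaged[name] = entry
        else:
            averaged[name] = average_similarity(list(entry))
    names = list(averaged)
    sim = pd.DataFrame(1.0, index=names, columns=names)
    for a, b in combinations(names, 2):
        coef = rank_correlation(
            averaged[a].lower_triangle, averaged[b].lower_triangle, method
        )
        sim.loc[a, b] = sim.loc[b, a] = coef
    dist = 1.0 - sim.to_numpy()
    np.fill_diagonal(dist, 0.0)
    tree = hierarchical_clustering(dist, labels=names, linkage=linkage)
    return sim, tree


def within_between_network_effect(
    cohort: Cohort,
    method: str = "kendall_tau_a",
    aggregation: str = "pairs",
) -> tuple[AnovaResult, pd.DataFrame]:
    """Membership (within/between network) x valence repeated-measures ANOVA.

    For each subject and valence context, every pair of ROIs is compared by
    rank-correlating their person-level similarity matrices; pair
    coefficients are averaged into a within-network and a between-network
    cell.  ``aggregation="pairs"`` weights every ROI pair equally;
    ``"network_balanced"`` first averages within each network and then
    across networks, weighting networks equally.  The 2x2 ANOVA
    (membership x valence) is run on the subject-level cell means.
    """
    networks = cohort.spec.networks()
    roi_names = [r for r in cohort.roi_names if networks[r] in ("DN", "SN")]
    if aggregation not in ("pairs", "network_balanced"):
        raise ValueError(f"unknown aggregation {aggregation!r}")

    cell_rows = []
    cells = np.zeros((len(cohort.subject_ids), 2, 2))  # membership x valence
    for s_idx, subject_id in enumerate(cohort.subject_ids):
        for v_idx, valence in enumerate((Valence.POSITIVE, Valence.NEGATIVE)):
            mats = {
                roi: condition_rdm(cohort.get(subject_id, roi), valence=valence)
                for roi in roi_names
            }
            within: dict[str, list[float]] = {}
            between: list[float] = []
            for a, b in combinations(roi_names, 2):
                coef = rank_correlation(
                    mats[a].lower_triangle, mats[b].lower_triangle, method
                )
                if np.isnan(coef):
                    continue
                if networks[a] == networks[b]:
                    within.setdefault(networks[a], []).append(coef)
                else:
                    between.append(coef)
            if not between or not any(within.values()):
                raise ValueError("a membership cell has no ROI pairs")
            if aggregation == "pairs":
                within_mean = float(np.mean(sum(within.values(), [])))
            else:
                within_mean = float(
                    np.mean([np.mean(v) for v in within.values() if v])
                )
            between_mean = float(np.mean(between))
            cells[s_idx, 0, v_idx] = within_mean
            cells[s_idx, 1, v_idx] = between_mean
            cell_rows.append(
                {
                    "subject": subject_id,
                    "valence": valence.label,
                    "within": within_mean,
                    "between": between_mean,
                }
            )
    anova = rm_anova_2x2(cells, factor_names=("membership", "valence"))
    return anova, pd.DataFrame(cell_rows)


# --------------------------------------------------------------------------- #
# Similarity / accuracy concordance
# --------------------------------------------------------------------------- #


def pairwise_person_accuracies(
    patterns: BetaPatterns,
    valence: Valence | None = None,
    settings: ClassifierSettings | None = None,
) -> dict[tuple[Person, Person], float]:
    """Leave-one-run-out accuracy for every pair of persons.

    With ``valence`` given, only that valence's conditions enter the
    binary classification, mirroring the per-context concordance analysis.
    """
    out = {}
    for a, b in combinations(Person, 2):
        conds = [
            c
            for c in CONDITIONS
            if c.person in (a, b) and (valence is None or c.valence is valence)
        ]
        scheme = DecodingScheme(
            name=f"{a.label}_vs_{b.label}",
            class_map={c: c.person.label for c in conds},
            classes=(a.label, b.label),
        )
        result, _ = cross_validate(patterns, scheme, settings)
        out[(a, b)] = result.accuracy
    return out


def similarity_accuracy_concordance(
    similarity: SimilarityMatrix,
    accuracies: Mapping[tuple[Person, Person], float],
    method: str = "spearman_rho",
) -> float:
    """Rank correlation between pairwise similarity and decoding accuracy.

    Expected negative under signal: the more similar two conditions'
    patterns, the more confusable they are for the classifier.  Returns
    NaN (undefined) when either vector is constant.
    """
    if similarity.level != FOUR_PERSON:
        raise ValueError("concordance is defined on person-level matrices")
    i, j = np.tril_indices(4, k=-1)
    sims, accs = [], []
    for row, col in zip(i, j):
        pair = (Person(min(row, col)), Person(max(row, col)))
        sims.append(similarity.values[row, col])
        accs.append(accuracies[pair])
    return rank_correlation(np.asarray(sims), np.asarray(accs), method)
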