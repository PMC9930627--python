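"""Decoding engines: leave-one-run-out cross-validation and cross-classification.

Seven decoding analyses probe different facets of self- versus
other-referential coding, all executed by a linear support vector machine
(C = 1) over condition-by-run beta vectors:

1. ``self_vs_other`` -- aggregate self ({PresentSelf, PastSelf}) versus
   aggregate other ({Mother, Queen});
2. ``present_vs_past`` -- PresentSelf versus PastSelf;
3. ``mother_vs_queen`` -- Mother versus Queen;
4. ``four_way`` -- 4-way person classification;
5. ``xclass_self_other_across_distance`` -- self/other trained on the
   socially near pair (PresentSelf vs Mother), tested on the far pair
   (PastSelf vs Queen), and the reverse;
6. ``xclass_distance_across_domain`` -- near/far trained within the self
   domain (PresentSelf vs PastSelf), tested within the other domain
   (Mother vs Queen), and the reverse;
7. ``xclass_four_way_across_valence`` -- 4-way person classification
   trained on positive-valence conditions, tested on negative (and the
   reverse).

Cross-validation schemes use a leave-one-run-out splitter (one fold per
run, so train and test runs never overlap); cross-classification schemes
train on one condition partition and test on a disjoint partition, in both
directions, averaging the two directional accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.svm import SVC

from .labels import CONDITIONS, ConditionLabel, Person, Valence

CROSS_VALIDATION = "cross_validation"
CROSS_CLASSIFICATION = "cross_classification"


class SchemeError(ValueError):
    """Raised for ill-formed or misused decoding schemes."""


@dataclass(frozen=True)
class ClassifierSettings:
    """Linear SVM settings: cost C (default 1, as in the original toolbox),
    an explicit one-vs-one multiclass strategy, and optional train-fold
    z-scoring (off by default; the analysis does not scale features)."""

    cost: float = 1.0
    multiclass: str = "ovo"
    scaling: str = "none"  # "none" | "train_fold_zscore"

    def __post_init__(self) -> None:
        if self.cost <= 0:
            raise ValueError("cost must be > 0")
        if self.multiclass != "ovo":
            raise ValueError("only the one-vs-one multiclass strategy is supported")
        if self.scaling not in ("none", "train_fold_zscore"):
            raise ValueError(f"unknown scaling {self.scaling!r}")


@dataclass(frozen=True)
class DecodingScheme:
    """Declarative description of one decoding analysis.

    ``class_map`` maps each participating condition to its class label;
    conditions absent from the map are excluded.  ``classes`` fixes the
    class order used for confusion matrices and deterministic tie-breaking.
    In cross-classification mode, ``train_conditions``/``test_conditions``
    give the two disjoint condition partitions.
    """

    name: str
    class_map: Mapping[ConditionLabel, str]
    mode: str = CROSS_VALIDATION
    classes: tuple[str, ...] = ()
    train_conditions: frozenset = frozenset()
    test_conditions: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "class_map", dict(self.class_map))
        if self.mode not in (CROSS_VALIDATION, CROSS_CLASSIFICATION):
            raise SchemeError(f"unknown mode {self.mode!r}")
        if not self.classes:
            object.__setattr__(
                self, "classes", tuple(sorted(set(self.class_map.values())))
            )
        if set(self.classes) != set(self.class_map.values()):
            raise SchemeError("classes must match the class_map labels")
        if self.mode == CROSS_CLASSIFICATION:
            train = frozenset(self.train_conditions)
            test = frozenset(self.test_conditions)
            if not train or not test:
                raise SchemeError(
                    "cross-classification requires train and test partitions"
                )
            if train & test:
                raise SchemeError("train and test condition sets must be disjoint")
            for cond in train | test:
                if cond not in self.class_map:
                    raise SchemeError(f"{cond} not covered by the class map")
            object.__setattr__(self, "train_conditions", train)
            object.__setattr__(self, "test_conditions", test)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def chance(self) -> float:
        return 1.0 / self.n_classes

    @property
    def conditions(self) -> tuple[ConditionLabel, ...]:
        return tuple(c for c in CONDITIONS if c in self.class_map)


SCHEME_NAMES = (
    "self_vs_other",
    "present_vs_past",
    "mother_vs_queen",
    "four_way",
    "xclass_self_other_across_distance",
    "xclass_distance_across_domain",
    "xclass_four_way_across_valence",
)

_PERSON_CLASSES = tuple(p.label for p in Person)


def make_scheme(name: str) -> DecodingScheme:
    """Return one of the seven standard decoding schemes by name."""
    if name == "self_vs_other":
        return DecodingScheme(
            name=name,
            class_map={c: c.person.domain for c in CONDITIONS},
            classes=("self", "other"),
        )
    if name == "present_vs_past":
        conds = [c for c in CONDITIONS if c.person in (Person.PRESENT_SELF, Person.PAST_SELF)]
        return DecodingScheme(
            name=name,
            class_map={c: c.person.label for c in conds},
            classes=("PresentSelf", "PastSelf"),
        )
    if name == "mother_vs_queen":
        conds = [c for c in CONDITIONS if c.person in (Person.MOTHER, Person.QUEEN)]
        return DecodingScheme(
            name=name,
            class_map={c: c.person.label for c in conds},
            classes=("Mother", "Queen"),
        )
    if name == "four_way":
        return DecodingScheme(
            name=name,
            class_map={c: c.person.label for c in CONDITIONS},
            classes=_PERSON_CLASSES,
        )
    if name == "xclass_self_other_across_distance":
        near = frozenset(
            c for c in CONDITIONS if c.person in (Person.PRESENT_SELF, Person.MOTHER)
        )
        far = frozenset(
            c for c in CONDITIONS if c.person in (Person.PAST_SELF, Person.QUEEN)
        )
        return DecodingScheme(
            name=name,
            class_map={c: c.person.domain for c in CONDITIONS},
            classes=("self", "other"),
            mode=CROSS_CLASSIFICATION,
            train_conditions=near,
            test_conditions=far,
        )
    if name == "xclass_distance_across_domain":
        self_dom = frozenset(
            c for c in CONDITIONS if c.person in (Person.PRESENT_SELF, Person.PAST_SELF)
        )
        other_dom = frozenset(
            c for c in CONDITIONS if c.person in (Person.MOTHER, Person.QUEEN)
        )
        return DecodingScheme(
            name=name,
            class_map={c: c.person.distance for c in CONDITIONS},
            classes=("near", "far"),
            mode=CROSS_CLASSIFICATION,
            train_conditions=self_dom,
            test_conditions=other_dom,
        )
    if name == "xclass_four_way_across_valence":
        positive = frozenset(c for c in CONDITIONS if c.valence is Valence.POSITIVE)
        negative = frozenset(c for c in CONDITIONS if c.valence is Valence.NEGATIVE)
        return DecodingScheme(
            name=name,
            class_map={c: c.person.label for c in CONDITIONS},
            classes=_PERSON_CLASSES,
            mode=CROSS_CLASSIFICATION,
            train_conditions=positive,
            test_conditions=negative,
        )
    raise KeyError(f"unknown decoding scheme {name!r}")


# --------------------------------------------------------------------------- #
# Results
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class AccuracyResult:
    accuracy: float
    per_fold: tuple[float, ...]
    chance: float
    n_folds: int

    def __post_init__(self) -> None:
        if not np.isclose(self.accuracy, float(np.mean(self.per_fold))):
            raise ValueError("accuracy must equal the mean of per-fold accuracies")


@dataclass(frozen=True)
class ConfusionMatrix:
    """True-class x predicted-class counts with a row-percentage view."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (len(self.classes), len(self.classes)):
            raise ValueError("counts must be square, aligned with classes")
        object.__setattr__(self, "counts", counts)

    @property
    def percentages(self) -> np.ndarray:
        row_sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(row_sums > 0, 100.0 * self.counts / row_sums, np.nan)

    def rate(self, true: str, predicted: str) -> float:
        return float(
            self.percentages[self.classes.index(true), self.classes.index(predicted)]
        )


# --------------------------------------------------------------------------- #
# Engines
# --------------------------------------------------------------------------- #


def _as_values(patterns) -> np.ndarray:
    values = getattr(patterns, "values", patterns)
    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise ValueError("patterns must be (n_conditions, n_runs, n_voxels)")
    return values


def train_and_predict(
    train_vectors: np.ndarray,
    train_labels: Sequence[str],
    test_vectors: np.ndarray,
    settings: ClassifierSettings | None = None,
    classes: Sequence[str] | None = None,
) -> np.ndarray:
    """Fit a linear SVM (C defaults to 1) and predict test labels.

    Multiclass problems use explicit one-vs-one voting; vote ties are broken
    toward the earliest class in ``classes`` (deterministic).
    """
    settings = settings or ClassifierSettings()
    X_train = np.asarray(train_vectors, dtype=float)
    X_test = np.asarray(test_vectors, dtype=float)
    y_train = np.asarray(train_labels)
    if X_train.ndim != 2 or X_test.ndim != 2 or X_train.shape[1] != X_test.shape[1]:
        raise ValueError("train and test vectors must share the feature dimension")
    if classes is None:
        classes = tuple(sorted(set(y_train.tolist())))
    classes = tuple(classes)
    present = set(y_train.tolist())
    missing = [c for c in classes if c not in present]
    if missing:
        raise ValueError(f"classes absent from training data: {missing}")

    if settings.scaling == "train_fold_zscore":
        mu = X_train.mean(axis=0)
        sd = X_train.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        X_train = (X_train - mu) / sd
        X_test = (X_test - mu) / sd

    def _fit_binary(a: str, b: str) -> np.ndarray:
        sel = (y_train == a) | (y_train == b)
        clf = SVC(kernel="linear", C=settings.cost)
        clf.fit(X_train[sel], y_train[sel])
        return clf.predict(X_test)

    if len(classes) == 2:
        return _fit_binary(classes[0], classes[1])

    votes = np.zeros((len(X_test), len(classes)), dtype=int)
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            pred = _fit_binary(classes[i], classes[j])
            votes[pred == classes[i], i] += 1
            votes[pred == classes[j], j] += 1
    # argmax resolves ties toward the lowest class index
    winners = np.argmax(votes, axis=1)
    return np.asarray([classes[w] for w in winners])


def _examples(
    values: np.ndarray,
    conditions: Iterable[ConditionLabel],
    class_map: Mapping[ConditionLabel, str],
    runs: Iterable[int],
) -> tuple[np.ndarray, np.ndarray]:
    X, y = [], []
    for cond in conditions:
        for run in runs:
            X.append(values[cond.index, run])
            y.append(class_map[cond])
    return np.asarray(X), np.asarray(y)


def cross_validate(
    patterns,
    scheme: DecodingScheme,
    settings: ClassifierSettings | None = None,
) -> tuple[AccuracyResult, ConfusionMatrix]:
    """Leave-one-run-out cross-validation: one fold per run.

    Within each fold the classifier trains on all runs but one and is
    tested on the held-out run, so no example ever appears on both sides
    of a split.  The overall accuracy is the mean of fold accuracies.
    """
    if scheme.mode != CROSS_VALIDATION:
        raise SchemeError(f"scheme {scheme.name!r} is not a cross-validation scheme")
    values = _as_values(patterns)
    n_runs = values.shape[1]
    if n_runs < 2:
        raise ValueError("leave-one-run-out requires >= 2 runs")
    conds = scheme.conditions
    counts = np.zeros((scheme.n_classes, scheme.n_classes), dtype=int)
    per_fold = []
    for held_out in range(n_runs):
        train_runs = [r for r in range(n_runs) if r != held_out]
        X_train, y_train = _examples(values, conds, scheme.class_map, train_runs)
        X_test, y_test = _examples(values, conds, scheme.class_map, [held_out])
        preds = train_and_predict(
            X_train, y_train, X_test, settings, classes=scheme.classes
        )
        per_fold.append(float(np.mean(preds == y_test)))
        for truth, pred in zip(y_test, preds):
            counts[scheme.classes.index(truth), scheme.classes.index(pred)] += 1
    result = AccuracyResult(
        accuracy=float(np.mean(per_fold)),
        per_fold=tuple(per_fold),
        chance=scheme.chance,
        n_folds=n_runs,
    )
    return result, ConfusionMatrix(counts=counts, classes=scheme.classes)


def cross_classify(
    patterns,
    scheme: DecodingScheme,
    settings: ClassifierSettings | None = None,
) -> tuple[AccuracyResult, ConfusionMatrix]:
    """Bidirectional cross-classification over disjoint condition partitions.

    Trains on all runs of one partition and tests on all runs of the other,
    in both directions, averaging the two directional accuracies (so the
    result is invariant to which partition is nominally "train").
    """
    if scheme.mode != CROSS_CLASSIFICATION:
        raise SchemeError(
            f"scheme {scheme.name!r} is not a cross-classification scheme"
        )
    values = _as_values(patterns)
    runs = range(values.shape[1])
    side_a = tuple(c for c in CONDITIONS if c in scheme.train_conditions)
    side_b = tuple(c for c in CONDITIONS if c in scheme.test_conditions)
    counts = np.zeros((scheme.n_classes, scheme.n_classes), dtype=int)
    per_direction = []
    for train_side, test_side in ((side_a, side_b), (side_b, side_a)):
        X_train, y_train = _examples(values, train_side, scheme.class_map, runs)
        X_test, y_test = _examples(values, test_side, scheme.class_map, runs)
        preds = train_and_predict(
            X_train, y_train, X_test, settings, classes=scheme.classes
        )
        per_direction.append(float(np.mean(preds == y_test)))
        for truth, pred in zip(y_test, preds):
            counts[scheme.classes.index(truth), scheme.classes.index(pred)] += 1
    result = AccuracyResult(
        accuracy=float(np.mean(per_direction)),
        per_fold=tuple(per_direction),
        chance=scheme.chance,
        n_folds=2,
    )
    return result, ConfusionMatrix(counts=counts, classes=scheme.classes)


def decode(
    patterns,
    scheme: DecodingScheme,
    settings: ClassifierSettings | None = None,
) -> tuple[AccuracyResult, ConfusionMatrix]:
    """Run the engine appropriate to the scheme's mode."""
    if scheme.mode == CROSS_VALIDATION:
        return cross_validate(patterns, scheme, settings)
    return cross_classify(patterns, scheme, settings)
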