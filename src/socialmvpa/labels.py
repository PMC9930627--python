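"""Condition labels for the 4 (person) x 2 (valence) factorial design.

The experimental design crosses four person-concepts -- the participant's
present self, their past self, their mother, and a famous but personally
unfamiliar other (the Queen) -- with the emotive valence of the trait
descriptions used to probe each concept.  The person factor carries an
ordinal social-distance position (0 = PresentSelf ... 3 = Queen), which
downstream analyses use as the graded axis nested within the bipartite
self/other split.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class Person(enum.IntEnum):
    """Target person, ordered by social distance from the present self."""

    PRESENT_SELF = 0
    PAST_SELF = 1
    MOTHER = 2
    QUEEN = 3

    @property
    def label(self) -> str:
        return _PERSON_LABELS[self]

    @property
    def domain(self) -> str:
        """Which side of the bipartite self/other divide the person falls on."""
        return "self" if self <= Person.PAST_SELF else "other"

    @property
    def distance(self) -> str:
        """Near/far position within the person's own domain.

        PresentSelf and Mother are the socially proximal member of their
        respective domains; PastSelf and Queen are the distal members.
        """
        return "near" if self in (Person.PRESENT_SELF, Person.MOTHER) else "far"

    @classmethod
    def from_label(cls, label: str) -> "Person":
        return _PERSON_FROM_LABEL[label]


_PERSON_LABELS = {
    Person.PRESENT_SELF: "PresentSelf",
    Person.PAST_SELF: "PastSelf",
    Person.MOTHER: "Mother",
    Person.QUEEN: "Queen",
}
_PERSON_FROM_LABEL = {v: k for k, v in _PERSON_LABELS.items()}


class Valence(enum.IntEnum):
    POSITIVE = 0
    NEGATIVE = 1

    @property
    def label(self) -> str:
        return "Positive" if self is Valence.POSITIVE else "Negative"

    @classmethod
    def from_label(cls, label: str) -> "Valence":
        return cls.POSITIVE if label == "Positive" else cls.NEGATIVE


@dataclass(frozen=True, order=True)
class ConditionLabel:
    """One of the 8 experimental conditions (person x valence)."""

    person: Person
    valence: Valence

    @property
    def index(self) -> int:
        """Canonical condition index in 0..7 (person-major ordering)."""
        return int(self.person) * 2 + int(self.valence)

    @property
    def label(self) -> str:
        return f"{self.person.label}/{self.valence.label}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


#: The 8 conditions in canonical (person-major) order.
CONDITIONS: tuple[ConditionLabel, ...] = tuple(
    ConditionLabel(p, v) for p in Person for v in Valence
)

#: The 4 persons in social-distance order.
PERSONS: tuple[Person, ...] = tuple(Person)

N_CONDITIONS = len(CONDITIONS)
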