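"""PAD emotion scoring and nearest-reference-emotion classification.

The PAD model places an affective state in a three-dimensional space:
Pleasure (valence), Arousal (activation) and Dominance (sense of control),
each coded here on a [-4, 4] semantic-differential scale. A measured
(P, A, D) triple is classified to the nearest of 14 basic emotions, each
with fixed reference coordinates, by Euclidean distance

    L_n = sqrt((P - p_n)^2 + (A - a_n)^2 + (D - d_n)^2),  n = 1..14,

and the winning emotion carries a binary positive/negative tendency label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "PADScore",
    "QuestionnaireResponse",
    "EmotionReference",
    "EmotionAssignment",
    "ValidationError",
    "score_pad",
    "pad_distance",
    "classify_emotion",
    "tendency_of",
    "default_emotion_table",
    "POSITIVE_EMOTIONS",
]

#: Relative tolerance at which two reference distances count as tied.
TIE_RTOL = 1e-12

#: Emotions carrying a positive tendency; the remaining nine are negative.
#: Eleven of the fourteen emotions have an empirically attested label in the
#: reference cohort; Optimism, Disgust and Hostility are assigned by the sign
#: of their reference pleasure coordinate.
POSITIVE_EMOTIONS = frozenset(
    {"Joy", "Optimism", "Relaxation", "Surprise", "Dependence"}
)


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class PADScore:
    """One respondent's pleasure/arousal/dominance triple.

    Values are dimensionless scale units in [-4, 4]. Scores aggregated from
    integer item ratings are integer multiples of 1/k where k is the number
    of items per dimension (quarter steps for the default 4-item layout).
    """

    p: float
    a: float
    d: float
    strict: bool = True

    def __post_init__(self) -> None:
        if self.strict:
            for dim, v in zip("pad", (self.p, self.a, self.d)):
                if not math.isfinite(v) or not -4.0 <= v <= 4.0:
                    raise ValidationError(
                        f"{dim} score {v!r} outside the [-4, 4] scale range"
                    )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p, self.a, self.d)


@dataclass(frozen=True)
class QuestionnaireResponse:
    """Item-level answers to a PAD semantic-differential scale.

    ``item_ratings`` holds one integer in [-4, 4] per item (9-point bipolar
    coding). ``dimension_map`` assigns each item to exactly one of 'p', 'a',
    'd'; ``reverse_flags`` marks reverse-keyed items whose sign is flipped
    before aggregation.
    """

    item_ratings: tuple[int, ...]
    dimension_map: tuple[str, ...]
    reverse_flags: tuple[bool, ...] = field(default=())

    def __post_init__(self) -> None:
        n = len(self.item_ratings)
        if not self.reverse_flags:
            object.__setattr__(self, "reverse_flags", (False,) * n)
        if len(self.dimension_map) != n or len(self.reverse_flags) != n:
            raise ValidationError(
                "item_ratings, dimension_map and reverse_flags must have equal length"
            )
        for i, r in enumerate(self.item_ratings):
            if not isinstance(r, (int,)) or isinstance(r, bool):
                raise ValidationError(f"item {i + 1}: rating {r!r} is not an integer")
            if not -4 <= r <= 4:
                raise ValidationError(f"item {i + 1}: rating {r} outside [-4, 4]")
        for i, dim in enumerate(self.dimension_map):
            if dim not in ("p", "a", "d"):
                raise ValidationError(
                    f"item {i + 1}: dimension {dim!r} not one of 'p', 'a', 'd'"
                )
        for dim in ("p", "a", "d"):
            if dim not in self.dimension_map:
                raise ValidationError(f"dimension {dim!r} has no items")


@dataclass(frozen=True)
class EmotionReference:
    """A named basic emotion with PAD reference coordinates and tendency."""

    index: int
    name: str
    p_ref: float
    a_ref: float
    d_ref: float
    tendency: str

    def __post_init__(self) -> None:
        if self.tendency not in ("positive", "negative"):
            raise ValidationError(
                f"tendency must be 'positive' or 'negative', got {self.tendency!r}"
            )


@dataclass(frozen=True)
class EmotionAssignment:
    """Nearest reference emotion for one score, with distance and tendency."""

    emotion_name: str
    distance: float
    tendency: str


# 14 basic emotions: (index, name, p_ref, a_ref, d_ref)
_REFERENCE_ROWS: tuple[tuple[int, str, float, float, float], ...] = (
    (1, "Joy", 2.77, 1.21, 1.42),
    (2, "Optimism", 2.48, 1.05, 1.75),
    (3, "Relaxation", 2.19, -0.66, 1.05),
    (4, "Surprise", 1.72, 1.71, 0.22),
    (5, "Gentleness", 1.57, -0.79, 0.38),
    (6, "Dependence", 0.39, -0.81, -1.48),
    (7, "Boredom", -0.53, -1.25, -0.84),
    (8, "Sadness", -0.89, 0.17, -0.7),
    (9, "Fear", -0.93, 1.3, -0.64),
    (10, "Anxiety", -0.95, 0.32, 1.02),
    (11, "Contempt", -1.58, 0.32, -0.63),
    (12, "Disgust", -1.8, 0.4, 0.67),
    (13, "Resentment", -1.98, 1.1, 0.6),
    (14, "Hostility", -2.09, 1.00, 1.12),
)


def default_emotion_table(
    positive: Iterable[str] = POSITIVE_EMOTIONS,
) -> list[EmotionReference]:
    """Return the 14 basic-emotion references with their tendency labels.

    ``positive`` overrides which emotion names map to a positive tendency;
    every other emotion is labelled negative.
    """
    positive = frozenset(positive)
    unknown = positive - {row[1] for row in _REFERENCE_ROWS}
    if unknown:
        raise ValidationError(f"unknown emotion names in positive set: {sorted(unknown)}")
    return [
        EmotionReference(
            index=i,
            name=name,
            p_ref=p,
            a_ref=a,
            d_ref=d,
            tendency="positive" if name in positive else "negative",
        )
        for i, name, p, a, d in _REFERENCE_ROWS
    ]


def score_pad(response: QuestionnaireResponse, strict: bool = True) -> PADScore:
    """Aggregate item ratings into a PAD score.

    Each dimension's score is the arithmetic mean of its item ratings after
    sign-flipping reverse-keyed items, so a k-item dimension yields scores on
    a 1/k grid within [-4, 4].
    """
    sums = {"p": 0.0, "a": 0.0, "d": 0.0}
    counts = {"p": 0, "a": 0, "d": 0}
    for rating, dim, rev in zip(
        response.item_ratings, response.dimension_map, response.reverse_flags
    ):
        sums[dim] += -rating if rev else rating
        counts[dim] += 1
    return PADScore(
        p=sums["p"] / counts["p"],
        a=sums["a"] / counts["a"],
        d=sums["d"] / counts["d"],
        strict=strict,
    )


def pad_distance(score: PADScore, ref: EmotionReference) -> float:
    """Euclidean distance from a PAD score to a reference emotion (L_n)."""
    return math.sqrt(
        (score.p - ref.p_ref) ** 2
        + (score.a - ref.a_ref) ** 2
        + (score.d - ref.d_ref) ** 2
    )


def classify_emotion(
    score: PADScore, table: Sequence[EmotionReference] | None = None
) -> EmotionAssignment:
    """Assign the nearest reference emotion by Euclidean distance.

    Ties (distances equal within ``TIE_RTOL`` relative tolerance) are broken
    by the lowest reference index, which makes the result deterministic
    under any permutation of ``table``.
    """
    if table is None:
        table = default_emotion_table()
    if not table:
        raise ValidationError("reference table is empty")
    names = [ref.name for ref in table]
    if len(set(names)) != len(names):
        raise ValidationError("reference table contains duplicate emotion names")

    best: EmotionReference | None = None
    best_dist = math.inf
    for ref in table:
        dist = pad_distance(score, ref)
        if best is None or dist < best_dist * (1.0 - TIE_RTOL):
            best, best_dist = ref, dist
        elif dist <= best_dist * (1.0 + TIE_RTOL) and ref.index < best.index:
            best, best_dist = ref, min(dist, best_dist)
    assert best is not None
    return EmotionAssignment(
        emotion_name=best.name, distance=best_dist, tendency=best.tendency
    )


def tendency_of(
    emotion_name: str, table: Sequence[EmotionReference] | None = None
) -> str:
    """Look up the positive/negative tendency of a named emotion."""
    if table is None:
        table = default_emotion_table()
    for ref in table:
        if ref.name == emotion_name:
            return ref.tendency
    raise ValidationError(f"unknown emotion name {emotion_name!r}")
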