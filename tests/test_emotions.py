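"""PAD scoring, reference-emotion distance and nearest-emotion assignment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from padeeg import (
    PADScore,
    QuestionnaireResponse,
    ValidationError,
    classify_emotion,
    default_emotion_table,
    pad_distance,
    score_pad,
    tendency_of,
)
from padeeg.emotions import POSITIVE_EMOTIONS

pad_floats = st.floats(min_value=-4.0, max_value=4.0, allow_nan=False)


def brute_force_nearest(p, a, d, table):
    """Independent argmin oracle: vectorized distance over the whole table."""
    coords = np.array([[r.p_ref, r.a_ref, r.d_ref] for r in table])
    dists = np.sqrt(((coords - np.array([p, a, d])) ** 2).sum(axis=1))
    return table[int(np.argmin(dists))].name, float(dists.min())


# ---------------------------------------------------------------- scoring

def make_response(p_items, a_items=(0,), d_items=(0,), reverse=None):
    ratings = tuple(p_items) + tuple(a_items) + tuple(d_items)
    dims = ("p",) * len(p_items) + ("a",) * len(a_items) + ("d",) * len(d_items)
    return QuestionnaireResponse(ratings, dims, reverse or ())


def test_score_pad_zero_items_give_zero_score():
    r = QuestionnaireResponse((0,) * 12, ("p", "a", "d") * 4)
    assert score_pad(r).as_tuple() == (0.0, 0.0, 0.0)


def test_score_pad_mean_has_quarter_step_granularity():
    r = make_response((3, 0, 0, 0))
    assert score_pad(r).p == 0.75


def test_score_pad_reverse_keyed_items_flip_sign():
    r = make_response((4, 4, 4, 4), reverse=(True, True, True, True, False, False))
    assert score_pad(r).p == -4.0


@pytest.mark.parametrize(
    "ratings, match",
    [((5, 0, 0), "item 1"), ((0, 2.5, 0), "item 2"), ((0, 0, -9), "item 3")],
)
def test_score_pad_rejects_bad_ratings_naming_the_item(ratings, match):
    with pytest.raises(ValidationError, match=match):
        QuestionnaireResponse(tuple(ratings), ("p", "a", "d"))


def test_empty_dimension_rejected():
    with pytest.raises(ValidationError, match="'d'"):
        QuestionnaireResponse((1, 2), ("p", "a"))


# ------------------------------------------------------------- distances

def test_distance_to_own_reference_is_zero(emotion_table):
    joy = emotion_table[0]
    assert pad_distance(PADScore(2.77, 1.21, 1.42), joy) == 0.0


def test_distance_visitor_to_gentleness(emotion_table):
    gentleness = emotion_table[4]
    d = pad_distance(PADScore(0.75, -1.75, 0.5), gentleness)
    assert d == pytest.approx(math.sqrt(0.82**2 + 0.96**2 + 0.12**2))
    assert d == pytest.approx(1.268, abs=5e-4)


def test_distance_between_extreme_references(emotion_table):
    joy, hostility = emotion_table[0], emotion_table[13]
    d = pad_distance(PADScore(joy.p_ref, joy.a_ref, joy.d_ref), hostility)
    assert d == pytest.approx(4.873, abs=1e-3)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(pad_floats, pad_floats, pad_floats, st.integers(0, 13))
def test_distance_nonnegative_and_symmetric(p, a, d, i):
    ref = default_emotion_table()[i]
    dist = pad_distance(PADScore(p, a, d), ref)
    assert dist >= 0.0
    # symmetry: swap score and reference coordinates
    swapped = pad_distance(
        PADScore(ref.p_ref, ref.a_ref, ref.d_ref),
        type(ref)(index=ref.index, name=ref.name, p_ref=p, a_ref=a, d_ref=d,
                  tendency=ref.tendency),
    )
    assert dist == pytest.approx(swapped, rel=1e-12)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(*([pad_floats] * 6), st.integers(0, 13))
def test_triangle_inequality(p1, a1, d1, p2, a2, d2, i):
    ref = default_emotion_table()[i]
    s1, s2 = PADScore(p1, a1, d1), PADScore(p2, a2, d2)
    direct = pad_distance(s1, ref)
    via = pad_distance(s2, ref) + math.dist((p1, a1, d1), (p2, a2, d2))
    assert direct <= via + 1e-9


# --------------------------------------------------------- classification

@pytest.mark.parametrize(
    "pad, expected",
    [
        ((0.75, -1.75, 0.5), "Gentleness"),
        ((1.25, 1.75, 0.5), "Surprise"),
        ((1.25, -2.5, -2.75), "Dependence"),
    ],
)
def test_worked_visitor_rows(pad, expected, emotion_table):
    assert classify_emotion(PADScore(*pad), emotion_table).emotion_name == expected


def test_neutral_origin_is_nearest_to_sadness(emotion_table):
    a = classify_emotion(PADScore(0, 0, 0), emotion_table)
    assert a.emotion_name == "Sadness"
    assert a.distance == pytest.approx(1.145, abs=5e-4)


def test_each_reference_classifies_to_itself(emotion_table):
    for ref in emotion_table:
        a = classify_emotion(
            PADScore(ref.p_ref, ref.a_ref, ref.d_ref), emotion_table
        )
        assert a.emotion_name == ref.name
        assert a.distance == 0.0
        assert a.tendency == ref.tendency


def test_agrees_with_brute_force_oracle(emotion_table, rng):
    pts = rng.uniform(-4, 4, size=(1000, 3))
    for p, a, d in pts:
        mine = classify_emotion(PADScore(p, a, d), emotion_table)
        oracle_name, oracle_dist = brute_force_nearest(p, a, d, emotion_table)
        assert mine.emotion_name == oracle_name
        assert mine.distance == pytest.approx(oracle_dist, rel=1e-12)


def test_permutation_invariance_off_ties(emotion_table, rng):
    shuffled = list(emotion_table)
    rng.shuffle(shuffled)
    for p, a, d in rng.uniform(-4, 4, size=(200, 3)):
        s = PADScore(p, a, d)
        assert (classify_emotion(s, emotion_table).emotion_name
                == classify_emotion(s, shuffled).emotion_name)


def test_exact_tie_broken_by_lowest_index(emotion_table):
    joy, optimism = emotion_table[0], emotion_table[1]
    mid = PADScore(
        (joy.p_ref + optimism.p_ref) / 2,
        (joy.a_ref + optimism.a_ref) / 2,
        (joy.d_ref + optimism.d_ref) / 2,
    )
    assert pad_distance(mid, joy) == pytest.approx(pad_distance(mid, optimism))
    assert classify_emotion(mid, emotion_table).emotion_name == "Joy"
    # same winner when the table is reversed
    assert classify_emotion(mid, list(reversed(emotion_table))).emotion_name == "Joy"


def test_small_perturbation_keeps_assignment(emotion_table, rng):
    # every other reference is > 2r away, so classification must stick
    r = 0.1
    for ref in emotion_table:
        direction = rng.standard_normal(3)
        direction *= r / np.linalg.norm(direction)
        s = PADScore(
            float(np.clip(ref.p_ref + direction[0], -4, 4)),
            float(np.clip(ref.a_ref + direction[1], -4, 4)),
            float(np.clip(ref.d_ref + direction[2], -4, 4)),
        )
        assert classify_emotion(s, emotion_table).emotion_name == ref.name


def test_empty_table_rejected():
    with pytest.raises(ValidationError):
        classify_emotion(PADScore(0, 0, 0), [])


# --------------------------------------------------------------- tendency

@pytest.mark.parametrize(
    "name, expected",
    [("Surprise", "positive"), ("Gentleness", "negative"),
     ("Dependence", "positive"), ("Joy", "positive"), ("Boredom", "negative")],
)
def test_tendency_lookup(name, expected):
    assert tendency_of(name) == expected


def test_unknown_emotion_rejected():
    with pytest.raises(ValidationError, match="Serenity"):
        tendency_of("Serenity")


def test_default_table_contents():
    table = default_emotion_table()
    assert len(table) == 14
    assert len({r.name for r in table}) == 14
    assert (table[0].name, table[0].p_ref, table[0].a_ref, table[0].d_ref) == (
        "Joy", 2.77, 1.21, 1.42)
    assert (table[6].name, table[6].p_ref, table[6].a_ref, table[6].d_ref) == (
        "Boredom", -0.53, -1.25, -0.84)
    assert {r.name for r in table if r.tendency == "positive"} == set(
        POSITIVE_EMOTIONS)


def test_printed_tendencies_consistent_with_lookup(reference_cohort):
    # every printed (state, tendency) pair matches the lookup table
    for _, row in reference_cohort.iterrows():
        assert tendency_of(row.state_printed) == row.tendency_printed.lower()


def test_strict_score_range_enforced_with_opt_out():
    with pytest.raises(ValidationError):
        PADScore(4.5, 0, 0)
    loose = PADScore(4.5, 0, 0, strict=False)
    assert loose.p == 4.5
    # the off-grid printed value 0.57 is in range, hence fine even when strict
    assert classify_emotion(PADScore(0.57, -0.75, -0.75)).emotion_name == "Dependence"
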