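"""Cohort-level descriptive statistics for PAD scores and tendencies.

Summaries follow survey-reporting conventions: sample (n-1) standard
deviation, even-n median as the mean of the two middle order statistics,
and half-away-from-zero display rounding (3 decimals for moments, 1 for
percentages).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .emotions import EmotionAssignment, ValidationError

__all__ = [
    "DimensionSummary",
    "TendencySummary",
    "GroupProfile",
    "round_display",
    "summarize_dimension",
    "summarize_tendency",
    "profile_by_group",
]


def round_display(x: float, decimals: int) -> float:
    """Round half away from zero to ``decimals`` places (display convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DimensionSummary:
    """Descriptives of one PAD dimension across a cohort.

    ``mean``/``sd``/``median`` are rounded to 3 decimals for display;
    ``share_pos``/``share_zero``/``share_neg`` are percentages of strictly
    positive, exactly zero and strictly negative values, to 1 decimal.
    Exact (unrounded) moments are kept alongside for further computation.
    """

    mean: float
    sd: float
    median: float
    share_pos: float
    share_zero: float
    share_neg: float
    mean_exact: float
    sd_exact: float
    median_exact: float
    n: int


@dataclass(frozen=True)
class TendencySummary:
    n_positive: int
    n_negative: int
    pct_negative: float


@dataclass(frozen=True)
class GroupProfile:
    """Tendency-by-category cross-tabulation for one demographic attribute."""

    attribute: str
    counts: pd.DataFrame  # rows: categories; columns: positive, negative, total
    modal_overall: str
    modal_positive: str
    modal_negative: str


def summarize_dimension(values: Sequence[float]) -> DimensionSummary:
    """Mean, sample sd, median and sign shares of one PAD dimension."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValidationError(
            f"need at least 2 values for a dimension summary, got {x.size}"
        )
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    median = float(np.median(x))
    n = x.size
    return DimensionSummary(
        mean=round_display(mean, 3),
        sd=round_display(sd, 3),
        median=round_display(median, 3),
        share_pos=round_display(100.0 * np.count_nonzero(x > 0) / n, 1),
        share_zero=round_display(100.0 * np.count_nonzero(x == 0) / n, 1),
        share_neg=round_display(100.0 * np.count_nonzero(x < 0) / n, 1),
        mean_exact=mean,
        sd_exact=sd,
        median_exact=median,
        n=n,
    )


def _tendency_label(item: EmotionAssignment | str) -> str:
    label = item.tendency if isinstance(item, EmotionAssignment) else item
    label = label.lower()
    if label not in ("positive", "negative"):
        raise ValidationError(f"unknown tendency label {label!r}")
    return label


def summarize_tendency(
    assignments: Iterable[EmotionAssignment | str],
) -> TendencySummary:
    """Count positive/negative tendencies and the negative percentage."""
    labels = [_tendency_label(a) for a in assignments]
    if not labels:
        raise ValidationError("no tendency labels to summarize")
    n_neg = labels.count("negative")
    n_pos = len(labels) - n_neg
    return TendencySummary(
        n_positive=n_pos,
        n_negative=n_neg,
        pct_negative=round_display(100.0 * n_neg / len(labels), 1),
    )


def profile_by_group(
    visitors: pd.DataFrame,
    attribute: str,
    categories: Sequence[str] | None = None,
) -> GroupProfile:
    """Cross-tabulate tendency by one demographic attribute.

    ``visitors`` needs a ``tendency`` column plus the attribute column.
    ``categories`` fixes the category universe so empty categories appear
    with zero counts. Modal categories (overall and within each tendency)
    break ties alphabetically.
    """
    if attribute not in visitors.columns:
        raise ValidationError(f"unknown demographic attribute {attribute!r}")
    if "tendency" not in visitors.columns:
        raise ValidationError("visitor table has no 'tendency' column")
    if visitors[attribute].isna().any():
        raise ValidationError(f"attribute {attribute!r} missing for some visitors")

    tendency = visitors["tendency"].map(_tendency_label)
    cats = list(categories) if categories is not None else sorted(
        visitors[attribute].astype(str).unique()
    )
    counts = pd.DataFrame(0, index=pd.Index(cats, name=attribute),
                          columns=["positive", "negative"], dtype=int)
    tab = pd.crosstab(visitors[attribute].astype(str), tendency)
    for col in ("positive", "negative"):
        if col in tab.columns:
            counts.loc[tab.index, col] = tab[col]
    counts["total"] = counts["positive"] + counts["negative"]

    def modal(col: str) -> str:
        # idxmax on an alphabetically sorted index → alphabetical tie-break
        ordered = counts[col].sort_index()
        return str(ordered.idxmax())

    return GroupProfile(
        attribute=attribute,
        counts=counts,
        modal_overall=modal("total"),
        modal_positive=modal("positive"),
        modal_negative=modal("negative"),
    )
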