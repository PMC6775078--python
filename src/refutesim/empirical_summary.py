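"""Small empirical summaries of labeled microblog data.

Three fully specified computations used to confront the simulator with a
real rumor-refutation episode: sentiment-count proportions, a per-day
emotion-trend series (topic heat + band proportions), and assignment of
refutation-speed (v) and credibility (a) ranks to media records.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SentimentCounts",
    "proportions_from_counts",
    "daily_emotion_trend",
    "assign_speed_credibility_ranks",
    "LABEL_SYNONYMS",
]

#: Accepted post labels; "neutral" and "immune" name the same middle band.
LABEL_SYNONYMS = {
    "negative": "negative",
    "neutral": "immune",
    "immune": "immune",
    "positive": "positive",
}


@dataclass(frozen=True)
class SentimentCounts:
    """Counts of labeled posts per sentiment class."""

    positive: int
    neutral: int
    negative: int

    def __post_init__(self) -> None:
        for name in ("positive", "neutral", "negative"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} count must be non-negative")

    @property
    def total(self) -> int:
        return self.positive + self.neutral + self.negative


def proportions_from_counts(
    counts: SentimentCounts, ndigits: int | None = 2
) -> tuple[float, float, float]:
    """Percentages (positive, neutral, negative) of the labeled posts.

    Each percentage is 100 * count / total; by default rounded to two
    decimals for display (pass ``ndigits=None`` for unrounded values, which
    sum to 100 exactly up to floating error).
    """
    total = counts.total
    if total <= 0:
        raise ValueError("cannot compute proportions of zero posts")
    pcts = (
        100.0 * counts.positive / total,
        100.0 * counts.neutral / total,
        100.0 * counts.negative / total,
    )
    if ndigits is None:
        return pcts
    return tuple(round(p, ndigits) for p in pcts)


def _normalize_labels(labels: pd.Series) -> pd.Series:
    lowered = labels.astype(str).str.strip().str.lower()
    unknown = sorted(set(lowered) - set(LABEL_SYNONYMS))
    if unknown:
        raise ValueError(
            f"unknown sentiment label(s) {unknown}; expected one of "
            f"{sorted(set(LABEL_SYNONYMS))}"
        )
    return lowered.map(LABEL_SYNONYMS)


def daily_emotion_trend(posts: pd.DataFrame) -> pd.DataFrame:
    """Per-calendar-day topic heat and emotion-band proportions.

    ``posts`` needs columns ``timestamp`` (parseable datetimes) and
    ``label`` (negative / neutral-or-immune / positive).  Days between the
    first and last post with zero posts are emitted with ``n_posts = 0`` and
    NaN proportions.  Unparseable timestamps raise with the offending row
    number.
    """
    required = {"timestamp", "label"}
    missing = required - set(posts.columns)
    if missing:
        raise ValueError(f"posts table lacks column(s): {sorted(missing)}")
    if posts.empty:
        return pd.DataFrame(
            columns=["date", "n_posts", "prop_negative", "prop_immune", "prop_positive"]
        )
    ts = pd.to_datetime(posts["timestamp"], errors="coerce")
    bad = np.nonzero(ts.isna().to_numpy())[0]
    if bad.size:
        raise ValueError(
            f"unparseable timestamp in row {int(bad[0])}: "
            f"{posts['timestamp'].iloc[int(bad[0])]!r}"
        )
    frame = pd.DataFrame({"date": ts.dt.date, "label": _normalize_labels(posts["label"])})
    tab = (
        frame.pivot_table(index="date", columns="label", aggfunc="size", fill_value=0)
        .reindex(columns=["negative", "immune", "positive"], fill_value=0)
    )
    full_days = pd.date_range(tab.index.min(), tab.index.max(), freq="D").date
    tab = tab.reindex(full_days, fill_value=0)
    n = tab.sum(axis=1)
    out = pd.DataFrame(
        {
            "date": tab.index,
            "n_posts": n.to_numpy(),
            "prop_negative": (tab["negative"] / n).to_numpy(),
            "prop_immune": (tab["immune"] / n).to_numpy(),
            "prop_positive": (tab["positive"] / n).to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def assign_speed_credibility_ranks(
    records: pd.DataFrame, event_start: date | str
) -> pd.DataFrame:
    """Assign refutation-speed and credibility ranks to media records.

    ``v_rank`` is 1 + whole days between ``event_start`` and the record's
    date (records on the event day are v1), capped at 3.  ``a_rank`` is the
    follower-count tertile across the records (top tertile -> a1).  Requires
    columns ``timestamp`` and ``followers``; the input order is irrelevant
    and the output preserves it.
    """
    required = {"timestamp", "followers"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"media table lacks column(s): {sorted(missing)}")
    if records.empty:
        raise ValueError("at least one media record is required")
    event_start = pd.Timestamp(event_start).date()
    ts = pd.to_datetime(records["timestamp"], errors="coerce")
    bad = np.nonzero(ts.isna().to_numpy())[0]
    if bad.size:
        raise ValueError(
            f"unparseable timestamp in row {int(bad[0])}: "
            f"{records['timestamp'].iloc[int(bad[0])]!r}"
        )
    days = np.array([(d.date() - event_start).days for d in ts])
    if (days < 0).any():
        first = int(np.nonzero(days < 0)[0][0])
        raise ValueError(
            f"record in row {first} predates event_start {event_start}"
        )
    v_rank = np.minimum(days + 1, 3).astype(int)
    followers = records["followers"].to_numpy(dtype=float)
    if (followers < 0).any():
        raise ValueError("follower counts must be non-negative")
    q1, q2 = np.quantile(followers, [1 / 3, 2 / 3])
    a_rank = np.where(followers > q2, 1, np.where(followers > q1, 2, 3)).astype(int)
    out = records.copy()
    out["v_rank"] = v_rank
    out["a_rank"] = a_rank
    return out
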