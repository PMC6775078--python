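"""Synthetic example inputs for the empirical-summary pipeline.

These generators emit small, valid tables of the shapes the
:mod:`refutesim.empirical_summary` functions consume: per-post sentiment
labels with timestamps, media records with follower/engagement columns, and
a sentiment-count table.  They emulate the *format* of a scraped microblog
dataset; they carry no real data.
"""

from __future__ import annotations

from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "synthetic_labeled_posts",
    "synthetic_media_records",
    "synthetic_sentiment_counts",
]


def synthetic_labeled_posts(
    n_posts: int = 400,
    n_days: int = 13,
    start: date | str = "2018-10-28",
    seed: int = 0,
) -> pd.DataFrame:
    """Labeled posts over an episode in which sentiment shifts from negative
    to positive/neutral as refutation proceeds (columns: timestamp, label)."""
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(start)
    # topic heat decays after an early peak
    day_weights = np.exp(-np.arange(n_days) / 4.0)
    day_weights /= day_weights.sum()
    days = rng.choice(n_days, size=n_posts, p=day_weights)
    seconds = rng.integers(0, 86400, size=n_posts)
    timestamps = [start + timedelta(days=int(d), seconds=int(s)) for d, s in zip(days, seconds)]
    # negative share fades with the day index, positive share grows
    p_neg = np.clip(0.7 - 0.06 * days, 0.05, None)
    p_pos = np.clip(0.15 + 0.05 * days, None, 0.8)
    p_neu = 1.0 - p_neg - p_pos
    u = rng.random(n_posts)
    labels = np.where(u < p_neg, "negative", np.where(u < p_neg + p_neu, "neutral", "positive"))
    frame = pd.DataFrame({"timestamp": timestamps, "label": labels})
    return frame.sort_values("timestamp", ignore_index=True)


def synthetic_media_records(
    n_records: int = 18,
    event_start: date | str = "2018-10-28",
    n_days: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Media refutation records (timestamp, followers, fans, posts,
    forward, comment, like) spread over the first ``n_days`` days."""
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(event_start)
    rows = []
    for i in range(n_records):
        day = i * n_days // n_records
        ts = start + timedelta(days=day, hours=int(rng.integers(8, 23)), minutes=int(rng.integers(0, 60)))
        followers = int(rng.lognormal(mean=15, sigma=2))
        rows.append(
            {
                "name": f"synthetic-media-{i:02d}",
                "timestamp": ts,
                "followers": followers,
                "fans": int(followers * rng.uniform(0.5, 1.5)),
                "posts": int(rng.integers(1_000, 200_000)),
                "forward": int(rng.integers(10, 50_000)),
                "comment": int(rng.integers(10, 20_000)),
                "like": int(rng.integers(10, 100_000)),
            }
        )
    return pd.DataFrame(rows)


def synthetic_sentiment_counts(
    n_total: int = 16083, seed: int = 0
) -> pd.DataFrame:
    """One-row sentiment-count table (columns positive, neutral, negative)
    with a plausible post-refutation mix (positive-leaning)."""
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_total, [0.4, 0.29, 0.31])
    return pd.DataFrame(
        [{"positive": int(counts[0]), "neutral": int(counts[1]), "negative": int(counts[2])}]
    )
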