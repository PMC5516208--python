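"""Mention-frequency series aligned to each member's community join date.

Each post is assigned a bin offset ``floor((t - t_first_post_of_author) /
bin_unit)`` in UTC days or 7-day weeks; a term's rate in a bin is its
mention count there divided by the total number of posts falling in that
bin offset (mentions per post). pt-attributed mentions and all mentions
are reported separately, so the pt series is a numerator subset of the
"all" series for every term and bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .catalogue import normalize_term
from .corpus import Corpus, CorpusError, MentionSpan, Post

_BIN_SECONDS = {"day": 86400, "week": 7 * 86400}


@dataclass
class AlignedSeries:
    """Rates per join-offset bin. Bins with zero posts are absent."""

    term: str
    attribution: str  # "pt" or "all"
    bin_unit: str
    values: dict[int, float] = field(default_factory=dict)
    support: dict[int, int] = field(default_factory=dict)


def join_offset(author_posts: Sequence[Post], post: Post, bin_unit: str = "week") -> int:
    """Bin index of a post relative to its author's first post."""
    if bin_unit not in _BIN_SECONDS:
        raise ValueError(f"unknown bin_unit {bin_unit!r}")
    if post.post_id not in {p.post_id for p in author_posts}:
        raise CorpusError(f"post {post.post_id!r} not by this author")
    first = author_posts[0].timestamp  # author index is time-sorted
    delta = (post.timestamp - first).total_seconds()
    return int(delta // _BIN_SECONDS[bin_unit])


def _post_bins(corpus: Corpus, bin_unit: str) -> dict[str, int]:
    """Bin offset of every post, keyed by post_id."""
    bins: dict[str, int] = {}
    secs = _BIN_SECONDS[bin_unit]
    for author_posts in corpus.authors.values():
        first = author_posts[0].timestamp
        for p in author_posts:
            bins[p.post_id] = int((p.timestamp - first).total_seconds() // secs)
    return bins


def aligned_series(
    corpus: Corpus,
    spans: Sequence[MentionSpan],
    term: str,
    attribution: str = "all",
    bin_unit: str = "week",
) -> AlignedSeries:
    """Mentions-per-post rate of one term per join-offset bin.

    The denominator is the number of posts (by any author) at that offset;
    an unknown term yields an empty series.
    """
    if bin_unit not in _BIN_SECONDS:
        raise ValueError(f"unknown bin_unit {bin_unit!r}")
    if attribution not in ("pt", "all"):
        raise ValueError("attribution must be 'pt' or 'all'")
    bins = _post_bins(corpus, bin_unit)
    support: dict[int, int] = {}
    for b in bins.values():
        support[b] = support.get(b, 0) + 1
    term = normalize_term(term)
    numer: dict[int, int] = {}
    for s in spans:
        if normalize_term(s.surface) != term:
            continue
        if attribution == "pt" and s.label != "pt":
            continue
        b = bins[s.post_id]
        numer[b] = numer.get(b, 0) + 1
    values = {b: numer.get(b, 0) / support[b] for b in sorted(support)}
    return AlignedSeries(
        term=term,
        attribution=attribution,
        bin_unit=bin_unit,
        values=values,
        support=dict(sorted(support.items())),
    )


def series_report(
    corpus: Corpus,
    spans: Sequence[MentionSpan],
    top_k: int = 5,
    bin_units: Sequence[str] = ("day", "week"),
) -> pd.DataFrame:
    """Long-format table (term, attribution, bin_unit, bin, rate, support)
    for the top-k most-mentioned terms, each as an "all" and a "pt" series."""
    from .catalogue import frequency_table

    top = frequency_table(spans, "all", top_k=top_k)["term"].tolist()
    rows = []
    for term in top:
        for unit in bin_units:
            for attr in ("all", "pt"):
                series = aligned_series(corpus, spans, term, attr, unit)
                for b, rate in series.values.items():
                    rows.append(
                        dict(
                            term=term, attribution=attr, bin_unit=unit,
                            bin=b, rate=rate, support=series.support[b],
                        )
                    )
    return pd.DataFrame(
        rows, columns=["term", "attribution", "bin_unit", "bin", "rate", "support"]
    )
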