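"""Per-user treatment catalogues and corpus-level frequency tables.

A user's catalogue aggregates every mention with the ``pt`` attribution —
the mentions that indicate actual usage by the patient of interest — into
(term, mention count, first/last date) entries. Frequency tables count raw
mentions per term and attribution; the user-count table counts each
(user, term) pair once, which is what separates "most discussed" from
"most used" treatments.

Term normalization is deliberately minimal (lowercase + whitespace
collapse): inflectional variants like "chelation"/"chelating" stay
distinct, matching how raw surface terms behave; an optional alias table
can merge them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import datetime
from typing import Mapping, Sequence

import pandas as pd

from .corpus import Corpus, CorpusError, MentionSpan

logger = logging.getLogger(__name__)

_WS = re.compile(r"\s+")


def normalize_term(surface: str, aliases: Mapping[str, str] | None = None) -> str:
    """Lowercase and collapse whitespace; apply the optional alias table."""
    term = _WS.sub(" ", surface.strip().lower())
    if aliases:
        term = aliases.get(term, term)
    return term


@dataclass
class CatalogueEntry:
    mention_count: int
    first_date: datetime
    last_date: datetime


@dataclass
class UserCatalogue:
    """All treatments attributed (pt) to one author's patient of interest."""

    author_id: str
    treatments: dict[str, CatalogueEntry] = field(default_factory=dict)


def build_catalogues(
    corpus: Corpus,
    spans: Sequence[MentionSpan],
    aliases: Mapping[str, str] | None = None,
) -> dict[str, UserCatalogue]:
    """Group pt-labeled mentions by author into treatment catalogues.

    Raises on spans referencing unknown posts. Authors with no pt mention
    get no catalogue.
    """
    catalogues: dict[str, UserCatalogue] = {}
    for s in spans:
        if s.label != "pt":
            continue
        post = corpus.post(s.post_id)  # raises CorpusError if unknown
        term = normalize_term(s.surface, aliases)
        cat = catalogues.setdefault(post.author_id, UserCatalogue(post.author_id))
        entry = cat.treatments.get(term)
        if entry is None:
            cat.treatments[term] = CatalogueEntry(1, post.timestamp, post.timestamp)
        else:
            entry.mention_count += 1
            entry.first_date = min(entry.first_date, post.timestamp)
            entry.last_date = max(entry.last_date, post.timestamp)
    return catalogues


def frequency_table(
    spans: Sequence[MentionSpan],
    attribution: str = "all",
    top_k: int | None = None,
    aliases: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Mention counts per normalized term for one attribution (or "all").

    Every mention counts (no per-user deduplication); rows are sorted by
    descending count, ties broken lexicographically by term.
    """
    counts: dict[str, int] = {}
    for s in spans:
        if attribution != "all" and s.label != attribution:
            continue
        term = normalize_term(s.surface, aliases)
        counts[term] = counts.get(term, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_k is not None:
        rows = rows[:top_k]
    return pd.DataFrame(rows, columns=["term", "mention_count"])


def user_count_table(
    catalogues: Mapping[str, UserCatalogue], top_k: int | None = None
) -> pd.DataFrame:
    """Distinct-user count per term: multiple mentions of a treatment by
    the same user count once."""
    counts: dict[str, int] = {}
    for cat in catalogues.values():
        for term in cat.treatments:
            counts[term] = counts.get(term, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_k is not None:
        rows = rows[:top_k]
    return pd.DataFrame(rows, columns=["term", "user_count"])


def treatments_per_user_histogram(
    catalogues: Mapping[str, UserCatalogue],
) -> dict[int, int]:
    """Histogram: number of distinct catalogued treatments -> number of
    users. Values sum to the number of catalogued users."""
    hist: dict[int, int] = {}
    for cat in catalogues.values():
        n = len(cat.treatments)
        hist[n] = hist.get(n, 0) + 1
    return hist


def catalogues_to_frame(catalogues: Mapping[str, UserCatalogue]) -> pd.DataFrame:
    rows = []
    for author_id in sorted(catalogues):
        cat = catalogues[author_id]
        for term in sorted(cat.treatments):
            e = cat.treatments[term]
            rows.append(
                dict(
                    author_id=author_id,
                    term=term,
                    count=e.mention_count,
                    first_date=e.first_date.isoformat(),
                    last_date=e.last_date.isoformat(),
                )
            )
    return pd.DataFrame(
        rows, columns=["author_id", "term", "count", "first_date", "last_date"]
    )
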