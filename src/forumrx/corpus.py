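"""Forum corpus data model, annotation I/O and the typed-BIO tag codec.

A corpus is an ordered collection of posts (post_id, author_id, thread_id,
timestamp, text) with a derived author index. Treatment mentions are stored
as character-offset spans carrying one of five attribution labels:

``pt``      actual usage (or usage history) by the patient of interest
``pt-gen``  tied to the patient but no actual usage indicated
``cg``      tied to the caregiver (usually the posting parent)
``others``  tied to some other specific individual
``gen``     not tied to anyone specific

Span boundaries and attribution are encoded jointly on tokens with a
typed-BIO alphabet of 11 symbols: ``O`` plus ``B-c``/``I-c`` for each
attribution class ``c``.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: Closed vocabulary of attribution labels, in canonical order.
ATTRIBUTION_LABELS = ("pt", "pt-gen", "cg", "others", "gen")

#: The 11-symbol typed-BIO tag alphabet; O first (index 0 matters for
#: deterministic tie-breaking in decoding).
TAG_ALPHABET = ("O",) + tuple(
    f"{p}-{c}" for c in ATTRIBUTION_LABELS for p in ("B", "I")
)


class CorpusError(ValueError):
    """Malformed corpus or annotation input."""


@dataclass(frozen=True)
class Post:
    """One forum message."""

    post_id: str
    author_id: str
    thread_id: str
    timestamp: datetime
    text: str

    def __post_init__(self) -> None:
        if not self.text:
            raise CorpusError(f"post {self.post_id!r}: empty text")
        if self.timestamp.tzinfo is None:
            object.__setattr__(
                self, "timestamp", self.timestamp.replace(tzinfo=timezone.utc)
            )


@dataclass(frozen=True)
class MentionSpan:
    """A treatment mention: half-open 0-based character span into the post
    text, with one attribution label.

    Token indices are sentence-relative and optional; character offsets are
    authoritative. ``surface`` must equal ``post.text[char_start:char_end]``.
    """

    post_id: str
    char_start: int
    char_end: int
    surface: str
    label: str
    token_start: int | None = None
    token_end: int | None = None

    def __post_init__(self) -> None:
        if not self.char_start < self.char_end:
            raise CorpusError(
                f"span on {self.post_id!r}: char_start must be < char_end "
                f"({self.char_start}, {self.char_end})"
            )
        if self.label not in ATTRIBUTION_LABELS:
            raise CorpusError(f"unknown attribution label {self.label!r}")

    def overlaps(self, other: "MentionSpan") -> bool:
        return (
            self.post_id == other.post_id
            and self.char_start < other.char_end
            and other.char_start < self.char_end
        )


class Corpus:
    """Ordered posts with a derived author index.

    The author index exactly partitions the posts; within each author the
    posts are sorted by timestamp (stable for ties).
    """

    def __init__(self, posts: Iterable[Post]):
        self.posts: list[Post] = list(posts)
        seen: set[str] = set()
        for p in self.posts:
            if p.post_id in seen:
                raise CorpusError(f"duplicate post_id {p.post_id!r}")
            seen.add(p.post_id)
        self._by_id = {p.post_id: p for p in self.posts}
        self.authors: dict[str, list[Post]] = {}
        for p in self.posts:
            self.authors.setdefault(p.author_id, []).append(p)
        for a in self.authors:
            self.authors[a].sort(key=lambda p: p.timestamp)

    def __len__(self) -> int:
        return len(self.posts)

    def __iter__(self):
        return iter(self.posts)

    def post(self, post_id: str) -> Post:
        try:
            return self._by_id[post_id]
        except KeyError:
            raise CorpusError(f"unknown post_id {post_id!r}") from None


def _parse_timestamp(value: str) -> datetime:
    ts = datetime.fromisoformat(value)
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


_POST_FIELDS = ("post_id", "author_id", "thread_id", "timestamp", "text")


def read_corpus(path, format: str = "jsonl", strict: bool = True) -> Corpus:
    """Read a corpus dump.

    ``jsonl``: one JSON object per line with the five post fields,
    ISO-8601 timestamp. ``csv``: same columns with a header row.

    In strict mode (default) a record with a missing or unparseable
    timestamp raises :class:`CorpusError` naming the line; in lenient mode
    such records are dropped and counted in the log.
    """
    if format not in ("jsonl", "csv"):
        raise CorpusError(f"unknown corpus format {format!r}")
    posts: list[Post] = []
    dropped = 0

    def build(record: dict, lineno: int) -> Post | None:
        nonlocal dropped
        missing = [f for f in _POST_FIELDS if f not in record or record[f] in (None, "")]
        try:
            if missing:
                raise CorpusError(f"missing field(s) {missing}")
            ts = _parse_timestamp(str(record["timestamp"]))
            return Post(
                post_id=str(record["post_id"]),
                author_id=str(record["author_id"]),
                thread_id=str(record["thread_id"]),
                timestamp=ts,
                text=str(record["text"]),
            )
        except (CorpusError, ValueError) as exc:
            if strict:
                raise CorpusError(f"{path}: line {lineno}: {exc}") from exc
            dropped += 1
            return None

    if format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    record = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusError(f"{path}: line {lineno}: bad JSON: {exc}") from exc
                post = build(record, lineno)
                if post is not None:
                    posts.append(post)
    else:
        with open(path, encoding="utf-8", newline="") as fh:
            for lineno, record in enumerate(csv.DictReader(fh), start=2):
                post = build(record, lineno)
                if post is not None:
                    posts.append(post)

    if dropped:
        logger.warning("read_corpus: dropped %d malformed record(s) from %s", dropped, path)
    if not posts:
        logger.warning("read_corpus: %s yielded an empty corpus", path)
    return Corpus(posts)


def write_corpus(corpus: Corpus, path) -> None:
    """Write a corpus as jsonl (the inverse of ``read_corpus`` jsonl mode)."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in corpus:
            fh.write(
                json.dumps(
                    {
                        "post_id": p.post_id,
                        "author_id": p.author_id,
                        "thread_id": p.thread_id,
                        "timestamp": p.timestamp.isoformat(),
                        "text": p.text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Typed-BIO codec
# ---------------------------------------------------------------------------

def is_valid_bio(tags: Sequence[str]) -> bool:
    """True iff every I-c is preceded by B-c or I-c of the same class."""
    prev = "O"
    for t in tags:
        if t not in TAG_ALPHABET:
            return False
        if t.startswith("I-"):
            c = t[2:]
            if prev not in (f"B-{c}", f"I-{c}"):
                return False
        prev = t
    return True


def spans_to_tags(
    tokens: Sequence[tuple[str, int, int]], spans: Sequence[MentionSpan]
) -> list[str]:
    """Encode character spans as per-token typed-BIO tags.

    ``tokens`` are (surface, char_start, char_end) triples for one sentence.
    Spans must align exactly to token boundaries and must not overlap.
    """
    tags = ["O"] * len(tokens)
    starts = {s: i for i, (_, s, _) in enumerate(tokens)}
    ends = {e: i for i, (_, _, e) in enumerate(tokens)}
    prev: MentionSpan | None = None
    for span in sorted(spans, key=lambda s: s.char_start):
        if prev is not None and span.char_start < prev.char_end:
            raise CorpusError(f"overlapping spans: {prev} / {span}")
        prev = span
        if span.char_start not in starts or span.char_end not in ends:
            raise CorpusError(
                f"span [{span.char_start}, {span.char_end}) {span.surface!r} "
                f"does not align to token boundaries"
            )
        i, j = starts[span.char_start], ends[span.char_end]
        if any(t != "O" for t in tags[i : j + 1]):
            raise CorpusError(f"overlapping spans at tokens {i}..{j}")
        tags[i] = f"B-{span.label}"
        for k in range(i + 1, j + 1):
            tags[k] = f"I-{span.label}"
    return tags


def tags_to_spans(
    tokens: Sequence[tuple[str, int, int]],
    tags: Sequence[str],
    post_id: str = "",
    text: str | None = None,
) -> tuple[list[MentionSpan], int]:
    """Decode typed-BIO tags into mention spans.

    Invalid sequences (an orphan ``I-c`` not continuing a ``c`` span) are
    repaired by promoting the orphan to ``B-c``; the number of repairs is
    returned alongside the spans so callers can log it. On valid input this
    is the exact inverse of :func:`spans_to_tags`.
    """
    if len(tags) != len(tokens):
        raise CorpusError(
            f"tag/token length mismatch: {len(tags)} vs {len(tokens)}"
        )
    for t in tags:
        if t not in TAG_ALPHABET:
            raise CorpusError(f"unknown tag symbol {t!r}")
    spans: list[MentionSpan] = []
    repairs = 0
    i = 0
    n = len(tags)
    while i < n:
        tag = tags[i]
        if tag == "O":
            i += 1
            continue
        if tag.startswith("I-"):
            repairs += 1  # orphan I promoted to B
        label = tag[2:]
        j = i + 1
        while j < n and tags[j] == f"I-{label}":
            j += 1
        cs, ce = tokens[i][1], tokens[j - 1][2]
        surface = (
            text[cs:ce]
            if text is not None
            else " ".join(tok for tok, _, _ in tokens[i:j])
        )
        spans.append(
            MentionSpan(
                post_id=post_id,
                char_start=cs,
                char_end=ce,
                surface=surface,
                label=label,
                token_start=i,
                token_end=j,
            )
        )
        i = j
    spans.sort(key=lambda s: s.char_start)
    return spans, repairs


# ---------------------------------------------------------------------------
# CoNLL-style annotation files
# ---------------------------------------------------------------------------

def write_conll(
    sentences: Sequence[Sequence[str]],
    tag_sequences: Sequence[Sequence[str]],
    path,
    post_breaks: Sequence[int] = (),
) -> None:
    """Write token/tag pairs, one ``token<TAB>tag`` per line, a blank line
    between sentences and an extra blank line at each post boundary.

    ``post_breaks`` lists sentence indices that start a new post.
    """
    if len(sentences) != len(tag_sequences):
        raise CorpusError("sentences and tag sequences differ in length")
    breaks = set(post_breaks)
    with open(path, "w", encoding="utf-8") as fh:
        for si, (toks, tags) in enumerate(zip(sentences, tag_sequences)):
            if len(toks) != len(tags):
                raise CorpusError(f"sentence {si}: token/tag length mismatch")
            if si > 0:
                fh.write("\n")
                if si in breaks:
                    fh.write("\n")
            for tok, tag in zip(toks, tags):
                fh.write(f"{tok}\t{tag}\n")


def read_conll(path) -> tuple[list[list[str]], list[list[str]], list[int]]:
    """Inverse of :func:`write_conll`; returns (sentences, tags, post_breaks)."""
    sentences: list[list[str]] = []
    tags: list[list[str]] = []
    post_breaks: list[int] = []
    cur_toks: list[str] = []
    cur_tags: list[str] = []
    blank_run = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                if cur_toks:
                    sentences.append(cur_toks)
                    tags.append(cur_tags)
                    cur_toks, cur_tags = [], []
                blank_run += 1
                if blank_run == 2:
                    post_breaks.append(len(sentences))
                continue
            blank_run = 0
            parts = line.split("\t")
            if len(parts) != 2:
                raise CorpusError(f"{path}: line {lineno}: expected token<TAB>tag")
            tok, tag = parts
            if tag not in TAG_ALPHABET:
                raise CorpusError(f"{path}: line {lineno}: unknown tag {tag!r}")
            cur_toks.append(tok)
            cur_tags.append(tag)
    if cur_toks:
        sentences.append(cur_toks)
        tags.append(cur_tags)
    return sentences, tags, post_breaks


# ---------------------------------------------------------------------------
# Span CSV files
# ---------------------------------------------------------------------------

_SPAN_COLUMNS = ("post_id", "char_start", "char_end", "surface", "label")


def write_spans(spans: Sequence[MentionSpan], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_SPAN_COLUMNS)
        for s in spans:
            w.writerow([s.post_id, s.char_start, s.char_end, s.surface, s.label])


def read_spans(path) -> list[MentionSpan]:
    spans: list[MentionSpan] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(_SPAN_COLUMNS) - set(reader.fieldnames):
            raise CorpusError(f"{path}: span file must have columns {_SPAN_COLUMNS}")
        for lineno, row in enumerate(reader, start=2):
            try:
                spans.append(
                    MentionSpan(
                        post_id=row["post_id"],
                        char_start=int(row["char_start"]),
                        char_end=int(row["char_end"]),
                        surface=row["surface"],
                        label=row["label"],
                    )
                )
            except (CorpusError, ValueError) as exc:
                raise CorpusError(f"{path}: line {lineno}: {exc}") from exc
    return spans


def check_span_surfaces(corpus: Corpus, spans: Iterable[MentionSpan]) -> None:
    """Assert surface/offset fidelity of spans against the corpus text."""
    for s in spans:
        text = corpus.post(s.post_id).text
        if text[s.char_start : s.char_end] != s.surface:
            raise CorpusError(
                f"span surface mismatch on {s.post_id!r}: "
                f"{text[s.char_start:s.char_end]!r} != {s.surface!r}"
            )
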