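"""Deterministic heuristic linguistic annotation.

Sentence splitting, tokenization, coarse POS tagging, lemmatization and a
subject/predicate heuristic, all rule-based and dependency-free, behind the
pluggable :class:`Annotator` interface. Real taggers or parsers can be
plugged in behind the same interface; everything downstream only relies on
the :class:`AnnotatedSentence` contract.

POS tags come from a fixed coarse 11-tag set:
NOUN VERB ADJ ADV PRON DET ADP NUM PUNCT SYM X
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Protocol, Sequence

POS_TAGS = (
    "NOUN", "VERB", "ADJ", "ADV", "PRON", "DET", "ADP", "NUM", "PUNCT", "SYM", "X",
)

_ABBREVIATIONS = {
    "dr.", "mr.", "mrs.", "ms.", "prof.", "st.", "jr.", "sr.",
    "e.g.", "i.e.", "etc.", "vs.", "approx.", "dept.", "fig.", "no.",
}

AUXILIARIES = {
    "is", "am", "are", "was", "were", "be", "been", "being",
    "has", "have", "had", "do", "does", "did",
    "will", "would", "shall", "should", "can", "could", "may", "might", "must",
}


@dataclass(frozen=True)
class AnnotatedSentence:
    """Token-level annotation of one sentence.

    ``tokens`` are (surface, char_start, char_end) with offsets into the
    original post text; ``pos`` and ``lemma`` are parallel lists;
    ``subject_index``/``predicate_index`` are token indices or None.
    """

    tokens: tuple[tuple[str, int, int], ...]
    pos: tuple[str, ...]
    lemma: tuple[str, ...]
    subject_index: int | None
    predicate_index: int | None

    def __post_init__(self) -> None:
        n = len(self.tokens)
        assert len(self.pos) == n and len(self.lemma) == n
        for idx in (self.subject_index, self.predicate_index):
            assert idx is None or 0 <= idx < n

    @property
    def surfaces(self) -> tuple[str, ...]:
        return tuple(t[0] for t in self.tokens)


class Annotator(Protocol):
    """Pluggable annotation interface: post text in, annotated sentences out.

    Implementations must be deterministic and offset-faithful: for every
    token, ``text[char_start:char_end] == surface``.
    """

    def annotate(self, text: str) -> list[AnnotatedSentence]:
        ...


def sentence_split(text: str) -> list[tuple[int, int]]:
    """Split text into sentence character spans.

    Boundaries are ``.``, ``!`` or ``?`` followed by whitespace and an
    upper-case letter (or end of text), guarded against a small
    abbreviation list. Spans are trimmed of surrounding whitespace, are
    disjoint and ordered, and jointly cover all non-whitespace text.
    """
    if not text.strip():
        return []
    boundaries = [0]
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch in ".!?":
            # lookbehind for abbreviation guard (only relevant for '.')
            if ch == ".":
                m = re.search(r"(\S+\.)$", text[: i + 1])
                if m and m.group(1).lower() in _ABBREVIATIONS:
                    i += 1
                    continue
            j = i + 1
            while j < n and text[j] in ".!?":
                j += 1
            k = j
            while k < n and text[k].isspace():
                k += 1
            if k == n:
                break
            if k > j and (text[k].isupper() or text[k].isdigit()):
                boundaries.append(k)
                i = k
                continue
            i = j
            continue
        i += 1
    boundaries.append(n)
    spans = []
    for a, b in zip(boundaries, boundaries[1:]):
        seg = text[a:b]
        lo = a + (len(seg) - len(seg.lstrip()))
        hi = a + len(seg.rstrip())
        if hi > lo:
            spans.append((lo, hi))
    return spans


_WORD_RE = re.compile(r"\S+")
# punctuation stripped off token edges; hyphen and slash are kept inside
_EDGE_PUNCT = ".,;:!?\"'()[]{}<>“”‘’…"


def tokenize(text: str, base_offset: int = 0) -> list[tuple[str, int, int]]:
    """Whitespace tokenization with edge punctuation split off.

    Hyphenated and slashed terms ("b-12", "gfcf/scd") stay whole. Offsets
    are relative to the original post text via ``base_offset``.
    """
    tokens: list[tuple[str, int, int]] = []
    for m in _WORD_RE.finditer(text):
        chunk, start = m.group(), base_offset + m.start()
        lo, hi = 0, len(chunk)
        lead: list[tuple[str, int, int]] = []
        while lo < hi and chunk[lo] in _EDGE_PUNCT:
            lead.append((chunk[lo], start + lo, start + lo + 1))
            lo += 1
        trail: list[tuple[str, int, int]] = []
        while hi > lo and chunk[hi - 1] in _EDGE_PUNCT:
            trail.append((chunk[hi - 1], start + hi - 1, start + hi))
            hi -= 1
        tokens.extend(lead)
        if hi > lo:
            tokens.append((chunk[lo:hi], start + lo, start + hi))
        tokens.extend(reversed(trail))
    return tokens


def _load_closed_class() -> dict[str, str]:
    lex: dict[str, str] = {}
    data = resources.files("forumrx.data").joinpath("closed_class.tsv").read_text("utf-8")
    for line in data.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        word, tag = line.split("\t")
        lex[word] = tag
    return lex


_CLOSED_CLASS: dict[str, str] | None = None


def closed_class_lexicon() -> dict[str, str]:
    global _CLOSED_CLASS
    if _CLOSED_CLASS is None:
        _CLOSED_CLASS = _load_closed_class()
    return _CLOSED_CLASS


_PUNCT_RE = re.compile(r"^\W+$", re.UNICODE)
_NUM_RE = re.compile(r"^[+-]?\d[\d.,/-]*$")

# irregular lemmas the suffix rules cannot reach
_IRREGULAR_LEMMAS = {
    "tried": "try", "tries": "try", "trying": "try",
    "took": "take", "taken": "take", "takes": "take", "taking": "take",
    "gave": "give", "given": "give", "gives": "give", "giving": "give",
    "started": "start", "put": "put", "said": "say", "says": "say",
    "went": "go", "goes": "go", "did": "do", "does": "do", "done": "do",
    "was": "be", "were": "be", "is": "be", "are": "be", "am": "be", "been": "be",
    "has": "have", "had": "have", "children": "child", "kids": "kid",
}


def _lemma(word: str) -> str:
    w = word.lower()
    if w in _IRREGULAR_LEMMAS:
        return _IRREGULAR_LEMMAS[w]
    if len(w) > 4 and w.endswith("ies"):
        return w[:-3] + "y"
    if len(w) > 3 and w.endswith("es") and w[-3] in "sxz":
        return w[:-2]
    if len(w) > 3 and w.endswith("s") and not w.endswith("ss") and not w.endswith("us"):
        return w[:-1]
    if len(w) > 5 and w.endswith("ing"):
        stem = w[:-3]
        if len(stem) > 2 and stem[-1] == stem[-2]:
            stem = stem[:-1]
        return stem
    if len(w) > 4 and w.endswith("ed"):
        stem = w[:-2]
        if len(stem) > 2 and stem[-1] == stem[-2]:
            stem = stem[:-1]
        elif stem.endswith(("at", "os", "iv", "ag", "ar", "id")):
            stem = stem + "e"
        return stem
    return w


def heuristic_pos_lemma(
    tokens: Sequence[str],
) -> tuple[list[str], list[str]]:
    """Coarse POS tags and lemmas by lexicon and suffix rules.

    Closed-class words come from a shipped ~300-entry lexicon; otherwise
    ``-ly`` → ADV, ``-ing``/``-ed`` (and third-person ``-s`` after a
    pronoun) → VERB, digits → NUM, pure punctuation → PUNCT, default NOUN.
    """
    lexicon = closed_class_lexicon()
    pos: list[str] = []
    for i, tok in enumerate(tokens):
        w = tok.lower()
        if w in lexicon:
            pos.append(lexicon[w])
        elif _NUM_RE.match(tok):
            pos.append("NUM")
        elif _PUNCT_RE.match(tok):
            pos.append("PUNCT" if all(c in _EDGE_PUNCT + "-/" for c in tok) else "SYM")
        elif w.endswith("ly") and len(w) > 3:
            pos.append("ADV")
        elif w in _IRREGULAR_LEMMAS and _IRREGULAR_LEMMAS[w] in (
            "try", "take", "give", "start", "put", "say", "go", "do",
        ):
            pos.append("VERB")
        elif (w.endswith("ing") or w.endswith("ed")) and len(w) > 4:
            pos.append("VERB")
        elif (
            w.endswith("s")
            and not w.endswith("ss")
            and len(w) > 3
            and i > 0
            and tokens[i - 1].lower() in ("he", "she", "it", "who")
        ):
            pos.append("VERB")
        else:
            pos.append("NOUN")
    lemmas = [_lemma(t) for t in tokens]
    return pos, lemmas


_SUBJECT_POS = {"PRON", "DET", "NOUN", "ADJ", "NUM"}


def find_subject_predicate(
    surfaces: Sequence[str], pos: Sequence[str]
) -> tuple[int | None, int | None]:
    """Heuristic sentence subject and main-verb predicate.

    Predicate: first non-auxiliary VERB; if every VERB is an auxiliary, the
    last auxiliary. Subject: head (last token) of the longest maximal
    PRON/DET/NOUN/ADJ run strictly before the predicate. (None, None) when
    the sentence has no verb.
    """
    verb_idx = [i for i, p in enumerate(pos) if p == "VERB"]
    if not verb_idx:
        return None, None
    pred = None
    for i in verb_idx:
        if surfaces[i].lower() not in AUXILIARIES:
            pred = i
            break
    if pred is None:
        pred = verb_idx[-1]
    # maximal runs of subject-like tokens strictly before the predicate
    best: tuple[int, int] | None = None  # (length, head index); ties → first run
    run_start = None
    for i in range(pred + 1):
        in_run = i < pred and pos[i] in _SUBJECT_POS
        if in_run and run_start is None:
            run_start = i
        if not in_run and run_start is not None:
            length = i - run_start
            if best is None or length > best[0]:
                best = (length, i - 1)
            run_start = None
    subject = best[1] if best is not None else None
    return subject, pred


class HeuristicAnnotator:
    """The shipped deterministic annotator implementing :class:`Annotator`."""

    def annotate(self, text: str) -> list[AnnotatedSentence]:
        out: list[AnnotatedSentence] = []
        for lo, hi in sentence_split(text):
            tokens = tokenize(text[lo:hi], base_offset=lo)
            if not tokens:
                continue
            surfaces = [t[0] for t in tokens]
            pos, lemmas = heuristic_pos_lemma(surfaces)
            subj, pred = find_subject_predicate(surfaces, pos)
            out.append(
                AnnotatedSentence(
                    tokens=tuple(tokens),
                    pos=tuple(pos),
                    lemma=tuple(lemmas),
                    subject_index=subj,
                    predicate_index=pred,
                )
            )
        return out


_ANNOTATORS = {"heuristic": HeuristicAnnotator}


def get_annotator(name: str = "heuristic") -> Annotator:
    """Look up a registered annotator implementation by name."""
    try:
        return _ANNOTATORS[name]()
    except KeyError:
        raise ValueError(
            f"unknown annotator {name!r}; registered: {sorted(_ANNOTATORS)}"
        ) from None


def register_annotator(name: str, factory) -> None:
    _ANNOTATORS[name] = factory
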