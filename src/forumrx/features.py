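"""Per-token feature extraction: lexical, semantic (gazetteer) and
syntactic families.

Every feature name carries a mandatory family prefix (``lex:``, ``sem:``,
``syn:``) so names never collide across families, and extraction is fully
deterministic. The family subset is the ablation axis of the evaluation
harness (lexical / lexical+semantic / lexical+semantic+syntactic).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

from .linguistic import AnnotatedSentence

FAMILIES = ("lexical", "semantic", "syntactic")

BOS = "<BOS>"
EOS = "<EOS>"

#: Signed token-distance buckets for syntactic features.
_DIST_BUCKETS = ((0, "0"), (1, "+1"), (-1, "-1"), (2, "+2"), (-2, "-2"))


def bucket_distance(d: int | None) -> str:
    """Bucket a signed token distance: 0, ±1, ±2, ±3-5, ±6+, none."""
    if d is None:
        return "none"
    for v, name in _DIST_BUCKETS:
        if d == v:
            return name
    sign = "+" if d > 0 else "-"
    return f"{sign}3-5" if abs(d) <= 5 else f"{sign}6+"


@dataclass(frozen=True)
class Gazetteer:
    """A case-insensitive term list for dictionary matching."""

    name: str
    terms: frozenset[str]
    max_term_tokens: int = field(init=False)

    def __post_init__(self) -> None:
        if not all(t for t in self.terms):
            raise ValueError("gazetteer terms must be non-empty")
        if any(t != t.lower() for t in self.terms):
            raise ValueError("gazetteer terms must be lowercase")
        object.__setattr__(
            self,
            "max_term_tokens",
            max((len(t.split()) for t in self.terms), default=0),
        )


def load_gazetteer(path, name: str | None = None) -> Gazetteer:
    """Load a gazetteer file: UTF-8, one term per line, ``#`` comments."""
    terms = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                terms.append(line.lower())
    return Gazetteer(name=name or str(path), terms=frozenset(terms))


def reference_gazetteer() -> Gazetteer:
    """The shipped ASD-treatment gazetteer (~170 terms: drugs, supplements,
    diets, behavioural and alternative therapies, plus variants)."""
    data = resources.files("forumrx.data").joinpath("gazetteer.txt").read_text("utf-8")
    terms = [
        ln.strip().lower()
        for ln in data.splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    return Gazetteer(name="treat", terms=frozenset(terms))


def gazetteer_match(tokens: Sequence[str], gazetteer: Gazetteer) -> list[str]:
    """Greedy leftmost-longest dictionary match over lowercased token
    n-grams (up to ``max_term_tokens``); returns per-token {B, I, O}."""
    lowered = [t.lower() for t in tokens]
    tags = ["O"] * len(tokens)
    i = 0
    while i < len(tokens):
        matched = 0
        for n in range(min(gazetteer.max_term_tokens, len(tokens) - i), 0, -1):
            if " ".join(lowered[i : i + n]) in gazetteer.terms:
                matched = n
                break
        if matched:
            tags[i] = "B"
            for k in range(i + 1, i + matched):
                tags[k] = "I"
            i += matched
        else:
            i += 1
    return tags


_USERNAME_RE = re.compile(r"^@\w+")


def _shape(token: str) -> str:
    cap = "C" if token[:1].isupper() else "l"
    dig = "d" if any(c.isdigit() for c in token) else "-"
    hyp = "h" if "-" in token else "-"
    return cap + dig + hyp


def lexical_features(
    sentence: AnnotatedSentence,
    i: int,
    usernames: frozenset[str] = frozenset(),
) -> dict[str, float]:
    """Token identity/lowercase/lemma/POS in a ±2 window, word shape, and
    sentence-level question/exclamation/username flags."""
    n = len(sentence.tokens)
    if not 0 <= i < n:
        raise IndexError(f"token index {i} out of range for sentence of {n}")
    feats: dict[str, float] = {}
    for off in (-2, -1, 0, 1, 2):
        j = i + off
        if 0 <= j < n:
            w = sentence.tokens[j][0]
            feats[f"lex:w{off:+d}={w}"] = 1.0
            feats[f"lex:lw{off:+d}={w.lower()}"] = 1.0
            feats[f"lex:lemma{off:+d}={sentence.lemma[j]}"] = 1.0
            feats[f"lex:pos{off:+d}={sentence.pos[j]}"] = 1.0
        else:
            pad = BOS if j < 0 else EOS
            feats[f"lex:w{off:+d}={pad}"] = 1.0
    w0 = sentence.tokens[i][0]
    feats[f"lex:shape={_shape(w0)}"] = 1.0
    surfaces = sentence.surfaces
    if "?" in surfaces:
        feats["lex:sent_q"] = 1.0
    if "!" in surfaces:
        feats["lex:sent_excl"] = 1.0
    if any(_USERNAME_RE.match(t) or t.lower() in usernames for t in surfaces):
        feats["lex:sent_user"] = 1.0
    return feats


def semantic_features(
    sentence: AnnotatedSentence,
    i: int,
    gazetteers: Sequence[Gazetteer],
    match_cache: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, float]:
    """Per-gazetteer B/I/O match tag at positions i-1, i, i+1."""
    feats: dict[str, float] = {}
    n = len(sentence.tokens)
    for g in gazetteers:
        tags = (
            match_cache[g.name]
            if match_cache is not None
            else gazetteer_match(sentence.surfaces, g)
        )
        for off in (-1, 0, 1):
            j = i + off
            tag = tags[j] if 0 <= j < n else "O"
            feats[f"sem:{g.name}{off:+d}={tag}"] = 1.0
    return feats


def syntactic_features(sentence: AnnotatedSentence, i: int) -> dict[str, float]:
    """Subject/predicate lemmas, bucketed signed token distances to each,
    and first-person-subject indicators."""
    feats: dict[str, float] = {}
    subj, pred = sentence.subject_index, sentence.predicate_index
    if subj is not None:
        feats[f"syn:subj_word={sentence.lemma[subj]}"] = 1.0
        feats[f"syn:dist_subj={bucket_distance(i - subj)}"] = 1.0
        if sentence.lemma[subj] in ("i", "we"):
            feats["syn:subj_is_first_person"] = 1.0
        # "my"/"our" anywhere inside the subject run
        k = subj
        while k >= 0 and sentence.pos[k] in ("PRON", "DET", "NOUN", "ADJ", "NUM"):
            if sentence.lemma[k] in ("my", "our"):
                feats["syn:subj_is_my_np"] = 1.0
                break
            k -= 1
    else:
        feats["syn:dist_subj=none"] = 1.0
    if pred is not None:
        feats[f"syn:pred_word={sentence.lemma[pred]}"] = 1.0
        feats[f"syn:dist_pred={bucket_distance(i - pred)}"] = 1.0
    else:
        feats["syn:dist_pred=none"] = 1.0
    return feats


def extract_all(
    sentence: AnnotatedSentence,
    families: Iterable[str],
    gazetteers: Sequence[Gazetteer] = (),
    usernames: frozenset[str] = frozenset(),
) -> list[dict[str, float]]:
    """Per-token union of the selected family vectors."""
    fams = tuple(families)
    if not fams:
        raise ValueError("families must be non-empty")
    for f in fams:
        if f not in FAMILIES:
            raise ValueError(f"unknown feature family {f!r}; valid: {FAMILIES}")
    cache = {
        g.name: gazetteer_match(sentence.surfaces, g) for g in gazetteers
    }
    out: list[dict[str, float]] = []
    for i in range(len(sentence.tokens)):
        feats: dict[str, float] = {}
        if "lexical" in fams:
            feats.update(lexical_features(sentence, i, usernames))
        if "semantic" in fams:
            feats.update(semantic_features(sentence, i, gazetteers, cache))
        if "syntactic" in fams:
            feats.update(syntactic_features(sentence, i))
        out.append(feats)
    return out
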