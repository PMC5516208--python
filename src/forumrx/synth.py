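"""Synthetic gold-annotated forum corpus generator.

Emulates the statistical structure the pipeline assumes: a population of
authors with join dates and posting timelines; posts made of sentences
instantiated from class-specific templates around gazetteer treatment
terms, yielding exact gold mention spans with the five attribution labels.
Terms are sampled with Zipf weights (heavy-tailed term frequencies, as in
real forum data); the attribution mixture defaults to the empirical label
proportions of manually annotated autism-forum data, with extra mass on
sentences carrying no mention at all.

``cue_ambiguity`` is the difficulty dial: the probability that a mention
sentence uses a template whose wording genuinely underdetermines the
class (shared between two classes), standing in for real-data hardness.
At 0 the corpus is separable from lexical cues alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from importlib import resources
from typing import Sequence

import numpy as np

from .corpus import ATTRIBUTION_LABELS, Corpus, CorpusError, MentionSpan, Post
from .features import Gazetteer, reference_gazetteer

__all__ = [
    "GeneratorConfig", "Template", "TemplateBank", "default_templates",
    "generate", "corrupt", "reference_gazetteer",
]

# Empirical per-class annotation counts from a 500-post manual annotation
# of autism-forum posts; they fix the default relative class frequencies.
_CLASS_COUNTS = {"pt": 1830, "pt-gen": 434, "cg": 95, "others": 210, "gen": 1635}
_NONE_MASS = 0.4  # sentences with no treatment mention


def _default_mixture() -> dict[str, float]:
    total = sum(_CLASS_COUNTS.values())
    mix = {c: (1.0 - _NONE_MASS) * n / total for c, n in _CLASS_COUNTS.items()}
    mix["none"] = _NONE_MASS
    return mix


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    ``posts_per_author`` is the mean of a geometric distribution (support
    >= 1); ``sentences_per_post`` the mean of 1 + Poisson. ``class_mixture``
    covers the five attribution classes plus "none" and must sum to 1.
    """

    n_authors: int = 100
    posts_per_author: float = 20.0
    sentences_per_post: float = 2.0
    class_mixture: dict[str, float] = field(default_factory=_default_mixture)
    zipf_exponent: float = 1.2
    cue_ambiguity: float = 0.2
    timespan_days: int = 730
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.class_mixture) != set(ATTRIBUTION_LABELS) | {"none"}:
            raise ValueError(
                "class_mixture must cover the 5 attribution labels plus 'none'"
            )
        if abs(sum(self.class_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("class_mixture must sum to 1 (within 1e-9)")
        if not 0.0 <= self.cue_ambiguity <= 1.0:
            raise ValueError("cue_ambiguity must be in [0, 1]")
        if self.n_authors < 1 or self.posts_per_author < 1:
            raise ValueError("need at least one author and one post per author")


@dataclass(frozen=True)
class Template:
    classes: tuple[str, ...]  # >1 entries => ambiguous wording
    text: str  # contains one {TREATMENT} slot unless classes == ("none",)

    @property
    def ambiguous(self) -> bool:
        return len(self.classes) > 1


class TemplateBank:
    """Per-class sentence templates with a TREATMENT slot."""

    SLOT = "{TREATMENT}"

    def __init__(self, templates: Sequence[Template]):
        self.templates = tuple(templates)
        for t in self.templates:
            is_filler = t.classes == ("none",)
            n_slots = t.text.count(self.SLOT)
            if not is_filler and n_slots != 1:
                raise ValueError(f"template needs exactly one slot: {t.text!r}")
            if is_filler and n_slots:
                raise ValueError(f"filler template must have no slot: {t.text!r}")
            for c in t.classes:
                if c != "none" and c not in ATTRIBUTION_LABELS:
                    raise ValueError(f"unknown template class {c!r}")
        self._unambiguous = {
            c: tuple(t for t in self.templates if t.classes == (c,))
            for c in ATTRIBUTION_LABELS
        }
        self._ambiguous = {
            c: tuple(t for t in self.templates if t.ambiguous and c in t.classes)
            for c in ATTRIBUTION_LABELS
        }
        self._fillers = tuple(t for t in self.templates if t.classes == ("none",))
        for c, ts in self._unambiguous.items():
            if not ts:
                raise ValueError(f"no unambiguous template for class {c!r}")
        if not self._fillers:
            raise ValueError("template bank needs filler ('none') sentences")

    @classmethod
    def from_file(cls, path_or_text) -> "TemplateBank":
        if isinstance(path_or_text, str) and "\n" in path_or_text:
            text = path_or_text
        else:
            with open(path_or_text, encoding="utf-8") as fh:
                text = fh.read()
        templates = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            classes, tmpl = line.split("\t")
            templates.append(
                Template(tuple(c.strip() for c in classes.split(",")), tmpl)
            )
        return cls(templates)


def default_templates() -> TemplateBank:
    data = resources.files("forumrx.data").joinpath("templates.tsv").read_text("utf-8")
    return TemplateBank.from_file(data)


def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1, dtype=float) ** exponent
    return w / w.sum()


def generate(
    config: GeneratorConfig,
    templates: TemplateBank | None = None,
    gazetteer: Gazetteer | None = None,
) -> tuple[Corpus, list[MentionSpan]]:
    """Sample a gold-annotated corpus; fully reproducible from the seed."""
    templates = templates or default_templates()
    gazetteer = gazetteer or reference_gazetteer()
    rng = np.random.default_rng(config.seed)
    terms = sorted(gazetteer.terms)
    term_w = _zipf_weights(len(terms), config.zipf_exponent)
    classes = list(config.class_mixture)
    class_p = np.array([config.class_mixture[c] for c in classes])

    epoch = datetime(2010, 1, 1, tzinfo=timezone.utc)
    posts: list[Post] = []
    gold: list[MentionSpan] = []
    n_threads = max(1, config.n_authors * 2)
    post_counter = 0
    for a in range(config.n_authors):
        author_id = f"user{a:05d}"
        # geometric posts-per-author (support >= 1, mean = posts_per_author)
        n_posts = int(rng.geometric(1.0 / config.posts_per_author))
        join_day = float(rng.uniform(0, config.timespan_days * 0.5))
        active = float(rng.uniform(1.0, config.timespan_days - join_day))
        offsets = np.sort(rng.uniform(0, active, size=n_posts))
        for k in range(n_posts):
            post_id = f"p{post_counter:07d}"
            post_counter += 1
            thread_id = f"t{int(rng.integers(0, n_threads)):05d}"
            ts = epoch + timedelta(days=join_day + float(offsets[k]))
            n_sent = 1 + int(rng.poisson(max(config.sentences_per_post - 1.0, 0.0)))
            text_parts: list[str] = []
            char_pos = 0
            spans_here: list[tuple[int, int, str, str]] = []
            for _ in range(n_sent):
                cls = classes[int(rng.choice(len(classes), p=class_p))]
                if cls == "none":
                    sent = templates._fillers[int(rng.integers(len(templates._fillers)))].text
                else:
                    amb = templates._ambiguous.get(cls, ())
                    use_amb = amb and rng.random() < config.cue_ambiguity
                    pool = amb if use_amb else templates._unambiguous[cls]
                    tmpl = pool[int(rng.integers(len(pool)))]
                    term = terms[int(rng.choice(len(terms), p=term_w))]
                    prefix, suffix = tmpl.text.split(TemplateBank.SLOT)
                    sent = prefix + term + suffix
                # capitalize sentence-initially (keeps offsets unchanged)
                sent = sent[0].upper() + sent[1:]
                if cls != "none":
                    start = char_pos + len(prefix)
                    end = start + len(term)
                    spans_here.append((start, end, sent[len(prefix):len(prefix) + len(term)], cls))
                text_parts.append(sent)
                char_pos += len(sent) + 1  # joining space
            text = " ".join(text_parts)
            posts.append(
                Post(
                    post_id=post_id, author_id=author_id, thread_id=thread_id,
                    timestamp=ts, text=text,
                )
            )
            for start, end, _, cls in spans_here:
                gold.append(
                    MentionSpan(
                        post_id=post_id,
                        char_start=start,
                        char_end=end,
                        surface=text[start:end],
                        label=cls,
                    )
                )
    corpus = Corpus(posts)
    # enforce the gold-span fidelity invariant on every generated corpus
    for s in gold:
        assert corpus.post(s.post_id).text[s.char_start:s.char_end] == s.surface
    return corpus, gold


def corrupt(
    corpus: Corpus,
    gold: Sequence[MentionSpan],
    typo_rate: float,
    seed: int = 0,
) -> tuple[Corpus, list[MentionSpan]]:
    """Character-level noise (adjacent swaps and drops) strictly outside
    gold spans, with gold offsets re-synchronized.

    The gold surface invariant (``text[start:end] == surface``) holds on
    the output; rate 0 returns an identical corpus.
    """
    if not 0.0 <= typo_rate < 1.0:
        raise ValueError("typo_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    by_post: dict[str, list[MentionSpan]] = {}
    for s in gold:
        by_post.setdefault(s.post_id, []).append(s)
    new_posts: list[Post] = []
    new_gold: list[MentionSpan] = []
    for post in corpus:
        spans = sorted(by_post.get(post.post_id, []), key=lambda s: s.char_start)
        protected = np.zeros(len(post.text), dtype=bool)
        for s in spans:
            protected[s.char_start:s.char_end] = True
        out: list[str] = []
        new_offset = np.empty(len(post.text) + 1, dtype=np.intp)
        i = 0
        n = len(post.text)
        while i < n:
            new_offset[i] = len(out)
            ch = post.text[i]
            if protected[i] or rng.random() >= typo_rate:
                out.append(ch)
                i += 1
                continue
            op = rng.random()
            if op < 0.5 and i + 1 < n and not protected[i + 1]:
                # swap with the next (also unprotected) character
                new_offset[i + 1] = len(out) + 1
                out.append(post.text[i + 1])
                out.append(ch)
                i += 2
            else:
                # drop, unless it would empty the text
                if len(out) == 0 and i + 1 == n:
                    out.append(ch)
                i += 1
        new_offset[n] = len(out)
        text = "".join(out)
        new_posts.append(replace(post, text=text))
        for s in spans:
            cs, ce = int(new_offset[s.char_start]), int(new_offset[s.char_end])
            new_gold.append(
                MentionSpan(
                    post_id=s.post_id, char_start=cs, char_end=ce,
                    surface=text[cs:ce], label=s.label,
                )
            )
            if text[cs:ce] != s.surface:
                raise CorpusError("corrupt broke a gold surface; this is a bug")
    return Corpus(new_posts), new_gold
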