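"""Glue between the corpus data model and the sequence models.

Turns (corpus, spans) into per-sentence training examples — the sentence is
the CRF sequence unit, since attribution is annotated locally without
cross-sentence context — and maps decoded tag sequences back to
character-offset mention spans on posts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from . import crf as _crf
from .corpus import Corpus, MentionSpan, spans_to_tags, tags_to_spans
from .features import Gazetteer, extract_all
from .linguistic import AnnotatedSentence, Annotator, HeuristicAnnotator

logger = logging.getLogger(__name__)


@dataclass
class SentenceExample:
    """One sentence with its features and (optionally) gold tags."""

    post_id: str
    text: str  # full post text (for surface extraction)
    sentence: AnnotatedSentence
    features: list[dict[str, float]]
    gold_tags: list[str] | None


def build_examples(
    corpus: Corpus,
    spans: Sequence[MentionSpan] | None,
    families: Sequence[str],
    gazetteers: Sequence[Gazetteer] = (),
    annotator: Annotator | None = None,
) -> list[SentenceExample]:
    """Annotate every post, extract features, and (when gold spans are
    given) encode sentence-local typed-BIO tags."""
    annotator = annotator or HeuristicAnnotator()
    by_post: dict[str, list[MentionSpan]] = {}
    if spans is not None:
        for s in spans:
            by_post.setdefault(s.post_id, []).append(s)
    examples: list[SentenceExample] = []
    for post in corpus:
        sentences = annotator.annotate(post.text)
        post_spans = sorted(by_post.get(post.post_id, []), key=lambda s: s.char_start)
        for sent in sentences:
            feats = extract_all(sent, families, gazetteers)
            gold = None
            if spans is not None:
                lo = sent.tokens[0][1]
                hi = sent.tokens[-1][2]
                local = [s for s in post_spans if lo <= s.char_start and s.char_end <= hi]
                gold = spans_to_tags(sent.tokens, local)
            examples.append(
                SentenceExample(
                    post_id=post.post_id,
                    text=post.text,
                    sentence=sent,
                    features=feats,
                    gold_tags=gold,
                )
            )
    return examples


def feature_names(examples: Sequence[SentenceExample]) -> list[str]:
    """Sorted union of feature names over a dataset (deterministic index)."""
    names: set[str] = set()
    for ex in examples:
        for fv in ex.features:
            names.update(fv)
    return sorted(names)


def train_crf(
    examples: Sequence[SentenceExample],
    config: _crf.TrainConfig = _crf.TrainConfig(),
    callback=None,
) -> _crf.CrfModel:
    """Build a CRF over the dataset's feature vocabulary and train it."""
    data = [
        (ex.features, ex.gold_tags) for ex in examples if ex.gold_tags is not None
    ]
    if not data:
        raise ValueError("no gold-tagged sentences to train on")
    model = _crf.CrfModel(
        feature_names(examples),
        l2_sigma=config.l2_sigma,
        masked=config.invalid_transition_mask,
    )
    return _crf.train(model, data, config, callback=callback)


def predict_spans(
    model: _crf.CrfModel, examples: Sequence[SentenceExample]
) -> tuple[list[MentionSpan], int]:
    """Viterbi-decode every sentence and return mention spans (post-level
    character offsets) plus the BIO repair count (0 when the transition
    mask is on)."""
    out: list[MentionSpan] = []
    repairs = 0
    for ex in examples:
        tags = _crf.viterbi(model, ex.features)
        spans, r = tags_to_spans(ex.sentence.tokens, tags, post_id=ex.post_id, text=ex.text)
        repairs += r
        out.extend(spans)
    if repairs:
        logger.info("predict_spans: repaired %d invalid BIO transition(s)", repairs)
    return out, repairs
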