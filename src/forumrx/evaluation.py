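"""Span-level evaluation, the three scoring regimes, and inter-annotator
agreement.

Matching is exact-boundary: a predicted span counts as a true positive only
if a gold span has identical (post_id, char_start, char_end) — and, in
typed regimes, an identical attribution label. An incomplete boundary or a
wrong label both count as an error (one FP plus one FN). Regimes:

``mention_only``  untyped boundary match (detection quality alone)
``five_class``    boundary + label over the 5 attribution classes, with a
                  micro average pooling tp/fp/fn across classes
``binary_pt``     labels merged to {pt, non-pt} on both sides, then the pt
                  class is scored

Inter-annotator agreement is Cohen's kappa computed at the token level over
the 6-way alphabet (5 labels + O); kappa is unit-sensitive, so the unit is
part of the contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import ATTRIBUTION_LABELS, Corpus, MentionSpan, spans_to_tags
from .linguistic import Annotator, HeuristicAnnotator

logger = logging.getLogger(__name__)

REGIMES = ("mention_only", "five_class", "binary_pt")


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


@dataclass
class ClassScore:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return _prf(self.tp, self.fp, self.fn)[0]

    @property
    def recall(self) -> float:
        return _prf(self.tp, self.fp, self.fn)[1]

    @property
    def f1(self) -> float:
        return _prf(self.tp, self.fp, self.fn)[2]


@dataclass
class EvalReport:
    regime: str
    per_class: dict[str, ClassScore]
    repair_count: int = 0

    @property
    def micro(self) -> ClassScore:
        return ClassScore(
            tp=sum(c.tp for c in self.per_class.values()),
            fp=sum(c.fp for c in self.per_class.values()),
            fn=sum(c.fn for c in self.per_class.values()),
        )

    def to_rows(self) -> list[dict]:
        rows = []
        for cls, sc in self.per_class.items():
            rows.append(
                dict(
                    regime=self.regime, **{"class": cls},
                    tp=sc.tp, fp=sc.fp, fn=sc.fn,
                    precision=sc.precision, recall=sc.recall, f1=sc.f1,
                )
            )
        m = self.micro
        rows.append(
            dict(
                regime=self.regime, **{"class": "micro"},
                tp=m.tp, fp=m.fp, fn=m.fn,
                precision=m.precision, recall=m.recall, f1=m.f1,
            )
        )
        return rows


def _check_no_overlap(spans: Sequence[MentionSpan], who: str) -> None:
    by_post: dict[str, list[MentionSpan]] = {}
    for s in spans:
        by_post.setdefault(s.post_id, []).append(s)
    for post_id, ss in by_post.items():
        ss = sorted(ss, key=lambda s: s.char_start)
        for a, b in zip(ss, ss[1:]):
            if b.char_start < a.char_end:
                raise ValueError(
                    f"{who} spans overlap on post {post_id!r}: "
                    f"[{a.char_start},{a.char_end}) / [{b.char_start},{b.char_end})"
                )


def match_spans(
    gold: Sequence[MentionSpan],
    pred: Sequence[MentionSpan],
    typed: bool = True,
) -> tuple[int, int, int, list[tuple[MentionSpan, MentionSpan]]]:
    """One-to-one exact-boundary matching; returns (tp, fp, fn, pairs)."""
    _check_no_overlap(gold, "gold")
    _check_no_overlap(pred, "pred")

    def key(s: MentionSpan):
        k = (s.post_id, s.char_start, s.char_end)
        return k + (s.label,) if typed else k

    gold_map = {key(s): s for s in gold}
    pairs = []
    tp = 0
    for p in pred:
        g = gold_map.pop(key(p), None)
        if g is not None:
            tp += 1
            pairs.append((g, p))
    fp = len(pred) - tp
    fn = len(gold) - tp
    return tp, fp, fn, pairs


def binary_merge(label: str) -> str:
    """Merge to the {pt, non-pt} scheme: pt stays, everything else
    (pt-gen, cg, others, gen) becomes non-pt."""
    if label not in ATTRIBUTION_LABELS:
        raise ValueError(f"unknown attribution label {label!r}")
    return "pt" if label == "pt" else "non-pt"


def prf_report(
    gold: Sequence[MentionSpan],
    pred: Sequence[MentionSpan],
    regime: str,
    repair_count: int = 0,
) -> EvalReport:
    """Score predictions against gold under one regime."""
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; valid: {REGIMES}")
    if regime == "mention_only":
        tp, fp, fn, _ = match_spans(gold, pred, typed=False)
        return EvalReport(regime, {"mention": ClassScore(tp, fp, fn)}, repair_count)

    if regime == "binary_pt":
        gold_l = [(s, binary_merge(s.label)) for s in gold]
        pred_l = [(s, binary_merge(s.label)) for s in pred]
        classes = ("pt",)  # only the pt class is of interest
    else:
        gold_l = [(s, s.label) for s in gold]
        pred_l = [(s, s.label) for s in pred]
        classes = ATTRIBUTION_LABELS

    # typed matching on (boundary, effective label)
    gold_map: dict[tuple, str] = {}
    for s, lab in gold_l:
        gold_map[(s.post_id, s.char_start, s.char_end)] = lab
    _check_no_overlap([s for s, _ in gold_l], "gold")
    _check_no_overlap([s for s, _ in pred_l], "pred")
    per = {c: ClassScore(0, 0, 0) for c in classes}
    matched_gold: set[tuple] = set()
    for s, lab in pred_l:
        k = (s.post_id, s.char_start, s.char_end)
        hit = k in gold_map and k not in matched_gold and gold_map[k] == lab
        if hit:
            matched_gold.add(k)
            if lab in per:
                per[lab].tp += 1
        elif lab in per:
            per[lab].fp += 1
    for s, lab in gold_l:
        k = (s.post_id, s.char_start, s.char_end)
        if k not in matched_gold and lab in per:
            per[lab].fn += 1
    return EvalReport(regime, per, repair_count)


# ---------------------------------------------------------------------------
# Cohen's kappa
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KappaResult:
    value: float
    observed_agreement: float
    expected_agreement: float
    degenerate: bool = False  # p_e == 1 (e.g. both annotators all-O)

    def __float__(self) -> float:
        return self.value


def cohen_kappa(labels_a: Sequence[str], labels_b: Sequence[str]) -> KappaResult:
    """Cohen's kappa over two aligned label sequences:
    ``(p_o - p_e) / (1 - p_e)`` with marginal-product expected agreement.

    When ``p_e == 1`` (both marginals concentrated on one label) kappa is
    undefined; by convention it is reported as 1.0 with the ``degenerate``
    flag set, and a warning is logged.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("annotations cover different token universes")
    if not labels_a:
        raise ValueError("empty annotations")
    n = len(labels_a)
    cats = sorted(set(labels_a) | set(labels_b))
    idx = {c: i for i, c in enumerate(cats)}
    conf = np.zeros((len(cats), len(cats)))
    for a, b in zip(labels_a, labels_b):
        conf[idx[a], idx[b]] += 1
    conf /= n
    p_o = float(np.trace(conf))
    p_e = float(conf.sum(axis=1) @ conf.sum(axis=0))
    if abs(1.0 - p_e) < 1e-12:
        logger.warning("cohen_kappa: expected agreement is 1, kappa undefined; reporting 1.0")
        return KappaResult(1.0, p_o, p_e, degenerate=True)
    return KappaResult((p_o - p_e) / (1.0 - p_e), p_o, p_e)


def token_kappa(
    corpus: Corpus,
    spans_a: Sequence[MentionSpan],
    spans_b: Sequence[MentionSpan],
    annotator: Annotator | None = None,
) -> KappaResult:
    """Token-level 6-way kappa (5 attribution labels + O) between two span
    annotations of the same posts. Both sides are projected onto the same
    deterministic tokenization; B/I distinctions collapse to the class."""
    annotator = annotator or HeuristicAnnotator()
    by_post_a: dict[str, list[MentionSpan]] = {}
    by_post_b: dict[str, list[MentionSpan]] = {}
    for s in spans_a:
        by_post_a.setdefault(s.post_id, []).append(s)
    for s in spans_b:
        by_post_b.setdefault(s.post_id, []).append(s)
    seq_a: list[str] = []
    seq_b: list[str] = []
    for post in corpus:
        for sent in annotator.annotate(post.text):
            lo, hi = sent.tokens[0][1], sent.tokens[-1][2]
            for side, by_post, seq in (("a", by_post_a, seq_a), ("b", by_post_b, seq_b)):
                local = [
                    s for s in by_post.get(post.post_id, ())
                    if lo <= s.char_start and s.char_end <= hi
                ]
                tags = spans_to_tags(sent.tokens, local)
                seq.extend(t[2:] if t != "O" else "O" for t in tags)
    return cohen_kappa(seq_a, seq_b)


# ---------------------------------------------------------------------------
# Ablation grid
# ---------------------------------------------------------------------------

def split_posts(
    corpus: Corpus, test_fraction: float = 0.3, seed: int = 0
) -> tuple[Corpus, Corpus]:
    """Deterministic train/test split by post."""
    if not corpus.posts:
        raise ValueError("cannot split an empty corpus")
    rng = np.random.default_rng(seed)
    ids = [p.post_id for p in corpus]
    perm = rng.permutation(len(ids))
    n_test = int(round(len(ids) * test_fraction))
    test_ids = {ids[i] for i in perm[:n_test]}
    return (
        Corpus([p for p in corpus if p.post_id not in test_ids]),
        Corpus([p for p in corpus if p.post_id in test_ids]),
    )


def ablation_run(
    corpus: Corpus,
    gold_spans: Sequence[MentionSpan],
    family_sets: Sequence[Sequence[str]],
    systems: Sequence[str] = ("crf", "baseline", "baseline_plus"),
    regimes: Sequence[str] = REGIMES,
    gazetteers=(),
    eval_gazetteer=None,
    test_fraction: float = 0.3,
    seed: int = 0,
    train_config=None,
    l1_lambda: float | str = 0.1,
) -> pd.DataFrame:
    """Train/evaluate the full system grid (family set x system x regime)
    on one split; returns a long-format report table.

    ``eval_gazetteer`` is the dictionary the baseline detector uses
    (defaults to the first of ``gazetteers``).
    """
    from . import crf as _crf
    from .baselines import run_baseline, run_baseline_plus, train_attribution_lr
    from .pipeline import build_examples, predict_spans, train_crf

    for s in systems:
        if s not in ("crf", "baseline", "baseline_plus"):
            raise ValueError(f"unknown system {s!r}")
    for r in regimes:
        if r not in REGIMES:
            raise ValueError(f"unknown regime {r!r}")
    train_config = train_config or _crf.TrainConfig()
    train_corpus, test_corpus = split_posts(corpus, test_fraction, seed)
    if not train_corpus.posts or not test_corpus.posts:
        raise ValueError("empty train or test split")
    train_post_ids = {p.post_id for p in train_corpus}
    gold_train = [s for s in gold_spans if s.post_id in train_post_ids]
    gold_test = [s for s in gold_spans if s.post_id not in train_post_ids]
    if eval_gazetteer is None and gazetteers:
        eval_gazetteer = gazetteers[0]

    rows = []
    for fams in family_sets:
        fams = tuple(fams)
        tr_ex = build_examples(train_corpus, gold_train, fams, gazetteers)
        te_ex = build_examples(test_corpus, None, fams, gazetteers)
        crf_model = train_crf(tr_ex, train_config)
        crf_spans, repairs = predict_spans(crf_model, te_ex)
        lr_model = None
        if "baseline" in systems or "baseline_plus" in systems:
            lr_model = train_attribution_lr(tr_ex, gold_train, l1_lambda=l1_lambda, seed=seed)
        preds: dict[str, tuple[list[MentionSpan], int]] = {}
        if "crf" in systems:
            preds["crf"] = (crf_spans, repairs)
        if "baseline" in systems:
            if eval_gazetteer is None:
                raise ValueError("baseline system requires an eval_gazetteer")
            preds["baseline"] = (run_baseline(te_ex, eval_gazetteer, lr_model), 0)
        if "baseline_plus" in systems:
            preds["baseline_plus"] = (run_baseline_plus(te_ex, crf_spans, lr_model), repairs)
        for system, (spans, reps) in preds.items():
            for regime in regimes:
                report = prf_report(gold_test, spans, regime, repair_count=reps)
                for row in report.to_rows():
                    rows.append(dict(system=system, families="+".join(fams), **row))
    return pd.DataFrame(rows)


def format_report(df: pd.DataFrame) -> str:
    """Human-readable fixed-width rendering of an ablation table."""
    out = []
    for (regime, system), grp in df.groupby(["regime", "system"], sort=True):
        out.append(f"== {regime} / {system} ==")
        sub = grp[["families", "class", "tp", "fp", "fn", "precision", "recall", "f1"]]
        out.append(sub.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        out.append("")
    return "\n".join(out)
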