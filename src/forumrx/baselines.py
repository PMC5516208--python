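"""Comparison systems.

* ``dict_detect`` — gazetteer dictionary matching for mention detection
  (the classic consumer-health-vocabulary lookup baseline; high precision,
  low recall on terms outside the dictionary).
* lasso multinomial logistic regression over aggregated span features for
  attribution classification.
* ``baseline+`` — hybrid: CRF-detected spans, logistic-regression labels;
  by construction it ties the CRF on mention-only evaluation and differs
  only in attribution.

The logistic fit is delegated to scikit-learn (saga solver, L1 penalty)
behind this module's interface; everything is deterministic given seed and
data order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .corpus import ATTRIBUTION_LABELS, MentionSpan
from .features import Gazetteer, gazetteer_match
from .pipeline import SentenceExample

#: λ grid searched when ``l1_lambda="cv"`` (5-fold, highest mean accuracy;
#: ties toward the sparser/stronger penalty).
CV_LAMBDA_GRID = (1.0, 0.3, 0.1, 0.03)


def span_features(
    example: SentenceExample, token_start: int, token_end: int
) -> dict[str, float]:
    """Aggregate per-token features over a candidate span.

    Union of the in-span token features (``in:`` prefix) plus the context
    features of the tokens just before the span start and at the span end
    (``ctx:`` prefix). Deterministic given sentence, span and families.
    """
    feats: dict[str, float] = {}
    for t in range(token_start, token_end):
        for name, v in example.features[t].items():
            feats[f"in:{name}"] = v
    n = len(example.features)
    for j, side in ((token_start - 1, "L"), (token_end, "R")):
        if 0 <= j < n:
            for name, v in example.features[j].items():
                feats[f"ctx:{side}:{name}"] = v
        else:
            feats[f"ctx:{side}:<pad>"] = 1.0
    return feats


@dataclass
class LogisticModel:
    """Multinomial lasso logistic classifier over span features."""

    classes: tuple[str, ...]
    vectorizer: DictVectorizer
    clf: LogisticRegression
    l1_lambda: float

    @property
    def weights(self) -> np.ndarray:
        return self.clf.coef_

    def save(self, path) -> None:
        payload = {
            "format_version": 1,
            "kind": "logistic",
            "classes": list(self.classes),
            "sk_classes": [str(c) for c in self.clf.classes_],
            "features": self.vectorizer.get_feature_names_out().tolist(),
            "coef": self.clf.coef_.ravel().tolist(),
            "intercept": self.clf.intercept_.tolist(),
            "l1_lambda": self.l1_lambda,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "LogisticModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("format_version") != 1 or payload.get("kind") != "logistic":
            raise ValueError(f"{path}: not a version-1 logistic model file")
        vec = DictVectorizer(sparse=True)
        names = payload["features"]
        vec.feature_names_ = list(names)
        vec.vocabulary_ = {f: i for i, f in enumerate(names)}
        clf = LogisticRegression()
        clf.classes_ = np.array(payload["sk_classes"])
        clf.coef_ = np.array(payload["coef"]).reshape(len(clf.classes_) if len(clf.classes_) > 2 else 1, -1)
        clf.intercept_ = np.array(payload["intercept"])
        model = cls(
            classes=tuple(payload["classes"]),
            vectorizer=vec,
            clf=clf,
            l1_lambda=payload["l1_lambda"],
        )
        return model


def _as_int32_csr(X):
    # sklearn's saga path requires 32-bit sparse indices
    if hasattr(X, "indices"):
        X = X.copy()
        X.indices = X.indices.astype(np.int32)
        X.indptr = X.indptr.astype(np.int32)
    return X


def _fit(X, y, l1_lambda: float, seed: int) -> LogisticRegression:
    clf = LogisticRegression(
        solver="saga",
        l1_ratio=1.0,  # pure lasso penalty
        C=1.0 / l1_lambda,
        max_iter=500,
        tol=1e-6,
        random_state=seed,
    )
    clf.fit(_as_int32_csr(X), y)
    return clf


def lr_train(
    feature_dicts: Sequence[Mapping[str, float]],
    labels: Sequence[str],
    l1_lambda: float | str = 0.1,
    seed: int = 0,
) -> LogisticModel:
    """Fit the lasso multinomial logistic attribution classifier.

    ``l1_lambda`` is the L1 penalty strength (sklearn ``C = 1/λ``); pass
    ``"cv"`` to select it by 5-fold cross-validation over
    :data:`CV_LAMBDA_GRID`. Raises on single-class data.
    """
    if len(feature_dicts) != len(labels) or not labels:
        raise ValueError("features and labels must be non-empty and aligned")
    present = sorted(set(labels))
    if len(present) < 2:
        raise ValueError("degenerate training data: only one class present")
    vec = DictVectorizer(sparse=True)
    X = vec.fit_transform(feature_dicts)
    y = np.asarray(labels)
    if l1_lambda == "cv":
        l1_lambda = _select_lambda_cv(X, y, seed)
    clf = _fit(X, y, float(l1_lambda), seed)
    classes = tuple(c for c in ATTRIBUTION_LABELS if c in present) + tuple(
        c for c in present if c not in ATTRIBUTION_LABELS
    )
    return LogisticModel(classes=classes, vectorizer=vec, clf=clf, l1_lambda=float(l1_lambda))


def _select_lambda_cv(X, y, seed: int, n_folds: int = 5) -> float:
    best = (-np.inf, 0.0)
    min_class = np.min(np.bincount(np.unique(y, return_inverse=True)[1]))
    folds = int(min(n_folds, max(2, min_class)))
    for lam in CV_LAMBDA_GRID:
        accs = []
        kf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        for tr, te in kf.split(X, y):
            clf = _fit(X[tr], y[tr], lam, seed)
            accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
        score = float(np.mean(accs))
        if score > best[0] + 1e-12 or (abs(score - best[0]) <= 1e-12 and lam > best[1]):
            best = (score, lam)
    return best[1]


def lr_scores(model: LogisticModel, feature_dict: Mapping[str, float]) -> dict[str, float]:
    """Per-class decision scores, keyed by class name."""
    X = _as_int32_csr(model.vectorizer.transform([dict(feature_dict)]))
    raw = model.clf.decision_function(X)
    sk = [str(c) for c in model.clf.classes_]
    if raw.ndim == 1:  # binary: score of classes_[1]
        return {sk[0]: float(-raw[0]), sk[1]: float(raw[0])}
    return {c: float(s) for c, s in zip(sk, raw[0])}


def lr_classify(model: LogisticModel, feature_dict: Mapping[str, float]) -> str:
    """Argmax class; ties break toward the lower canonical class index."""
    scores = lr_scores(model, feature_dict)
    best = model.classes[0]
    for c in model.classes:
        if scores[c] > scores[best] + 0.0:
            best = c
    return best


# ---------------------------------------------------------------------------
# Mention-detection baseline and composed systems
# ---------------------------------------------------------------------------

def dict_detect(example: SentenceExample, gazetteer: Gazetteer) -> list[MentionSpan]:
    """Leftmost-longest dictionary matches as unlabeled candidate spans
    (label field set to a placeholder ``gen``; callers relabel)."""
    tags = gazetteer_match(example.sentence.surfaces, gazetteer)
    spans: list[MentionSpan] = []
    i = 0
    toks = example.sentence.tokens
    while i < len(tags):
        if tags[i] == "B":
            j = i + 1
            while j < len(tags) and tags[j] == "I":
                j += 1
            cs, ce = toks[i][1], toks[j - 1][2]
            spans.append(
                MentionSpan(
                    post_id=example.post_id,
                    char_start=cs,
                    char_end=ce,
                    surface=example.text[cs:ce],
                    label="gen",
                    token_start=i,
                    token_end=j,
                )
            )
            i = j
        else:
            i += 1
    return spans


def train_attribution_lr(
    examples: Sequence[SentenceExample],
    gold_spans: Sequence[MentionSpan],
    l1_lambda: float | str = 0.1,
    seed: int = 0,
) -> LogisticModel:
    """Train the logistic attribution classifier on gold spans with
    span-aggregated features."""
    by_post: dict[str, list[SentenceExample]] = {}
    for ex in examples:
        by_post.setdefault(ex.post_id, []).append(ex)
    fvs, ys = [], []
    for s in gold_spans:
        ex = _sentence_for(by_post.get(s.post_id, ()), s)
        if ex is None:
            continue
        ts, te = _token_range(ex, s)
        fvs.append(span_features(ex, ts, te))
        ys.append(s.label)
    return lr_train(fvs, ys, l1_lambda=l1_lambda, seed=seed)


def _sentence_for(examples, span: MentionSpan):
    for ex in examples:
        lo, hi = ex.sentence.tokens[0][1], ex.sentence.tokens[-1][2]
        if lo <= span.char_start and span.char_end <= hi:
            return ex
    return None


def _token_range(ex: SentenceExample, span: MentionSpan) -> tuple[int, int]:
    ts = te = None
    for k, (_, cs, ce) in enumerate(ex.sentence.tokens):
        if cs == span.char_start:
            ts = k
        if ce == span.char_end:
            te = k + 1
    if ts is None or te is None:
        # span does not align exactly; cover all overlapping tokens
        ts = min(
            (k for k, (_, cs, ce) in enumerate(ex.sentence.tokens) if ce > span.char_start),
            default=0,
        )
        te = max(
            (k + 1 for k, (_, cs, ce) in enumerate(ex.sentence.tokens) if cs < span.char_end),
            default=ts + 1,
        )
    return ts, te


def _relabel(
    examples: Sequence[SentenceExample],
    spans: Sequence[MentionSpan],
    lr_model: LogisticModel,
) -> list[MentionSpan]:
    by_post: dict[str, list[SentenceExample]] = {}
    for ex in examples:
        by_post.setdefault(ex.post_id, []).append(ex)
    out = []
    for s in spans:
        ex = _sentence_for(by_post.get(s.post_id, ()), s)
        if ex is None:
            out.append(s)
            continue
        ts, te = _token_range(ex, s)
        label = lr_classify(lr_model, span_features(ex, ts, te))
        out.append(
            MentionSpan(
                post_id=s.post_id,
                char_start=s.char_start,
                char_end=s.char_end,
                surface=s.surface,
                label=label,
                token_start=s.token_start,
                token_end=s.token_end,
            )
        )
    return out


def run_baseline(
    examples: Sequence[SentenceExample],
    gazetteer: Gazetteer,
    lr_model: LogisticModel,
) -> list[MentionSpan]:
    """Dictionary-matched spans, each labeled by the logistic classifier."""
    detected = [s for ex in examples for s in dict_detect(ex, gazetteer)]
    return _relabel(examples, detected, lr_model)


def run_baseline_plus(
    examples: Sequence[SentenceExample],
    crf_spans: Sequence[MentionSpan],
    lr_model: LogisticModel,
) -> list[MentionSpan]:
    """CRF-detected spans (attribution stripped), labels from the logistic
    classifier. Span set equals the CRF's exactly."""
    return _relabel(examples, crf_spans, lr_model)
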