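"""Linear-chain conditional random field over the 11-symbol typed-BIO
alphabet.

The model scores a tag sequence y for a sentence with per-token feature
vectors x as

    score(y | x) = sum_t  w_state . f(x_t, y_t)  +  sum_t  w_trans[y_{t-1}, y_t]

with dedicated BOS->y_1 and y_T->EOS transition entries, and defines
p(y | x) proportional to exp(score). Training maximizes the L2-regularized
conditional log-likelihood (a convex objective) with L-BFGS; inference uses
Viterbi, and forward-backward supplies the partition function and
marginals. An optional transition mask forbids sequences that violate the
BIO grammar (O -> I-c, B-c -> I-c' for c != c', BOS -> I-c), so decoded
output is always valid BIO.

All computation is in log space; everything is deterministic given data
order and configuration (weights initialize at zero; Viterbi ties break
toward the lower label index).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .corpus import TAG_ALPHABET

NEG_INF = -np.inf


@dataclass(frozen=True)
class TrainConfig:
    """Training settings for :func:`train`.

    ``l2_sigma`` is the Gaussian-prior scale: the penalty is
    ``sum(w^2) / (2 sigma^2)``, so smaller sigma means stronger shrinkage.
    ``invalid_transition_mask`` forbids BIO-invalid transitions during both
    training and decoding. ``seed`` is reserved for any sampling; the
    optimization itself is deterministic (zero initialization).
    """

    max_iterations: int = 100
    gradient_tolerance: float = 1e-5
    l2_sigma: float = 10.0
    seed: int = 0
    invalid_transition_mask: bool = True

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.l2_sigma <= 0 or self.gradient_tolerance <= 0:
            raise ValueError("l2_sigma and gradient_tolerance must be positive")


def bio_transition_mask(labels: Sequence[str]) -> np.ndarray:
    """Boolean (L+1, L+1) matrix of allowed transitions.

    Row L is BOS, column L is EOS. An ``I-c`` may only follow ``B-c`` or
    ``I-c`` of the same class; every label may end the sequence.
    """
    L = len(labels)
    allowed = np.ones((L + 1, L + 1), dtype=bool)
    for j, nxt in enumerate(labels):
        if not nxt.startswith("I-"):
            continue
        c = nxt[2:]
        for i, prev in enumerate(labels):
            if prev not in (f"B-{c}", f"I-{c}"):
                allowed[i, j] = False
        allowed[L, j] = False  # BOS -> I-c
    allowed[L, L] = False  # BOS -> EOS (empty sequences are not modeled)
    return allowed


class CrfModel:
    """Label set, feature index and weights of a linear-chain CRF.

    Weights live in one flat vector: first ``n_features x L`` state weights
    (feature-major), then the ``(L+1) x (L+1)`` transition block including
    BOS row and EOS column.
    """

    def __init__(
        self,
        feature_names: Sequence[str],
        labels: Sequence[str] = TAG_ALPHABET,
        l2_sigma: float = 10.0,
        masked: bool = True,
    ):
        self.labels = tuple(labels)
        self.label_index = {y: k for k, y in enumerate(self.labels)}
        self.feature_index = {f: k for k, f in enumerate(feature_names)}
        L = len(self.labels)
        self.state_weights = np.zeros((len(self.feature_index), L))
        self.trans_weights = np.zeros((L + 1, L + 1))
        self.l2_sigma = float(l2_sigma)
        self.masked = bool(masked)
        self.allowed = (
            bio_transition_mask(self.labels)
            if masked
            else np.ones((L + 1, L + 1), dtype=bool)
        )
        self.trained = False

    # -- weight vector view -------------------------------------------------

    @property
    def n_parameters(self) -> int:
        return self.state_weights.size + self.trans_weights.size

    def get_weights(self) -> np.ndarray:
        return np.concatenate([self.state_weights.ravel(), self.trans_weights.ravel()])

    def set_weights(self, w: np.ndarray) -> None:
        L = len(self.labels)
        ns = self.state_weights.size
        self.state_weights = w[:ns].reshape(-1, L).copy()
        self.trans_weights = w[ns:].reshape(L + 1, L + 1).copy()
        if self.masked:
            self.trans_weights[~self.allowed] = 0.0

    # -- encoding -----------------------------------------------------------

    def encode(
        self, feature_vectors: Sequence[Mapping[str, float]]
    ) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Map per-token feature dicts to (index array, value array) pairs;
        unknown feature names are ignored (standard at test time)."""
        ids, vals = [], []
        for fv in feature_vectors:
            pairs = [(self.feature_index[f], v) for f, v in fv.items() if f in self.feature_index]
            pairs.sort()
            ids.append(np.array([p[0] for p in pairs], dtype=np.intp))
            vals.append(np.array([p[1] for p in pairs], dtype=float))
        return ids, vals

    def encode_tags(self, tags: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.label_index[t] for t in tags], dtype=np.intp)
        except KeyError as exc:
            raise ValueError(f"unknown tag {exc.args[0]!r}") from None

    def state_scores(
        self, ids: Sequence[np.ndarray], vals: Sequence[np.ndarray]
    ) -> np.ndarray:
        """(T, L) matrix of per-position per-label state scores."""
        L = len(self.labels)
        S = np.zeros((len(ids), L))
        for t, (fid, fv) in enumerate(zip(ids, vals)):
            if len(fid):
                S[t] = fv @ self.state_weights[fid]
        return S

    def _log_trans(self) -> np.ndarray:
        lt = self.trans_weights.copy()
        lt[~self.allowed] = NEG_INF
        return lt

    # -- serialization ------------------------------------------------------

    FORMAT_VERSION = 1

    def save(self, path) -> None:
        payload = {
            "format_version": self.FORMAT_VERSION,
            "kind": "crf",
            "labels": list(self.labels),
            "features": sorted(self.feature_index, key=self.feature_index.get),
            "l2_sigma": self.l2_sigma,
            "masked": self.masked,
            "trained": self.trained,
            "state_weights": self.state_weights.ravel().tolist(),
            "trans_weights": self.trans_weights.ravel().tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "CrfModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("format_version") != cls.FORMAT_VERSION or payload.get("kind") != "crf":
            raise ValueError(f"{path}: not a version-{cls.FORMAT_VERSION} CRF model file")
        model = cls(
            payload["features"],
            labels=payload["labels"],
            l2_sigma=payload["l2_sigma"],
            masked=payload["masked"],
        )
        L = len(model.labels)
        model.state_weights = np.array(payload["state_weights"]).reshape(-1, L)
        model.trans_weights = np.array(payload["trans_weights"]).reshape(L + 1, L + 1)
        model.trained = payload["trained"]
        return model


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def score_sequence(
    model: CrfModel,
    feature_vectors: Sequence[Mapping[str, float]],
    tags: Sequence[str],
) -> float:
    """Unnormalized log-score of one tag sequence (state + transition sums,
    including BOS and EOS transitions)."""
    if len(feature_vectors) != len(tags):
        raise ValueError("feature/tag length mismatch")
    ids, vals = model.encode(feature_vectors)
    y = model.encode_tags(tags)
    S = model.state_scores(ids, vals)
    L = len(model.labels)
    total = float(S[np.arange(len(y)), y].sum())
    total += model.trans_weights[L, y[0]]  # BOS
    for t in range(1, len(y)):
        total += model.trans_weights[y[t - 1], y[t]]
    total += model.trans_weights[y[-1], L]  # EOS
    return float(total)


def _lse(M: np.ndarray, axis: int) -> np.ndarray:
    """Log-sum-exp along one axis, tolerating -inf entries (but not a
    fully -inf reduction, which valid transition masks never produce)."""
    m = M.max(axis=axis)
    with np.errstate(invalid="ignore"):
        return m + np.log(np.exp(M - np.expand_dims(m, axis)).sum(axis=axis))


def _forward(S: np.ndarray, lt: np.ndarray, L: int) -> np.ndarray:
    T = S.shape[0]
    alpha = np.empty((T, L))
    alpha[0] = lt[L, :L] + S[0]
    for t in range(1, T):
        alpha[t] = _lse(alpha[t - 1][:, None] + lt[:L, :L], axis=0) + S[t]
    return alpha


def _backward(S: np.ndarray, lt: np.ndarray, L: int) -> np.ndarray:
    T = S.shape[0]
    beta = np.empty((T, L))
    beta[T - 1] = lt[:L, L]
    for t in range(T - 2, -1, -1):
        beta[t] = _lse(lt[:L, :L] + S[t + 1] + beta[t + 1], axis=1)
    return beta


def log_partition(
    model: CrfModel, feature_vectors: Sequence[Mapping[str, float]]
) -> float:
    """log Z by the forward algorithm in log space."""
    if not feature_vectors:
        raise ValueError("sequence length must be >= 1")
    ids, vals = model.encode(feature_vectors)
    S = model.state_scores(ids, vals)
    L = len(model.labels)
    lt = model._log_trans()
    alpha = _forward(S, lt, L)
    return float(logsumexp(alpha[-1] + lt[:L, L]))


def viterbi(
    model: CrfModel, feature_vectors: Sequence[Mapping[str, float]]
) -> list[str]:
    """Most probable tag sequence; ties break toward lower label index."""
    if not feature_vectors:
        return []
    ids, vals = model.encode(feature_vectors)
    S = model.state_scores(ids, vals)
    L = len(model.labels)
    lt = model._log_trans()
    T = S.shape[0]
    delta = lt[L, :L] + S[0]
    back = np.zeros((T, L), dtype=np.intp)
    for t in range(1, T):
        cand = delta[:, None] + lt[:L, :L]  # (prev, next)
        back[t] = np.argmax(cand, axis=0)  # first max -> lowest prev index
        delta = cand[back[t], np.arange(L)] + S[t]
    delta = delta + lt[:L, L]
    y = np.empty(T, dtype=np.intp)
    y[T - 1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        y[t - 1] = back[t, y[t]]
    return [model.labels[k] for k in y]


def marginals(
    model: CrfModel, feature_vectors: Sequence[Mapping[str, float]]
) -> np.ndarray:
    """(T, L) posterior per-position label probabilities (forward-backward)."""
    if not feature_vectors:
        raise ValueError("sequence length must be >= 1")
    ids, vals = model.encode(feature_vectors)
    S = model.state_scores(ids, vals)
    L = len(model.labels)
    lt = model._log_trans()
    alpha = _forward(S, lt, L)
    beta = _backward(S, lt, L)
    logZ = logsumexp(alpha[-1] + lt[:L, L])
    return np.exp(alpha + beta - logZ)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class EncodedExample:
    """One pre-encoded training sentence, with features flattened across
    positions for vectorized scoring and gradient accumulation."""

    T: int
    flat_ids: np.ndarray  # feature index per active (position, feature) pair
    flat_vals: np.ndarray  # value per pair
    flat_pos: np.ndarray  # token position per pair
    tags: np.ndarray


def _flatten(ids, vals) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pos = np.concatenate(
        [np.full(len(a), t, dtype=np.intp) for t, a in enumerate(ids)]
    ) if ids else np.empty(0, dtype=np.intp)
    fid = np.concatenate(ids) if ids else np.empty(0, dtype=np.intp)
    fv = np.concatenate(vals) if vals else np.empty(0)
    return fid, fv, pos


def encode_dataset(
    model: CrfModel,
    data: Iterable[tuple[Sequence[Mapping[str, float]], Sequence[str]]],
) -> list[EncodedExample]:
    out = []
    for fvs, tags in data:
        if len(fvs) != len(tags) or not fvs:
            raise ValueError("each example needs matching non-empty features/tags")
        ids, vals = model.encode(fvs)
        fid, fv, pos = _flatten(ids, vals)
        out.append(
            EncodedExample(
                T=len(fvs), flat_ids=fid, flat_vals=fv, flat_pos=pos,
                tags=model.encode_tags(tags),
            )
        )
    return out


def _flat_state_scores(model: CrfModel, ex: EncodedExample) -> np.ndarray:
    S = np.zeros((ex.T, len(model.labels)))
    if len(ex.flat_ids):
        np.add.at(
            S, ex.flat_pos, ex.flat_vals[:, None] * model.state_weights[ex.flat_ids]
        )
    return S


def _nll_gradient_encoded(
    model: CrfModel, batch: Sequence[EncodedExample], w: np.ndarray
) -> tuple[float, np.ndarray]:
    model.set_weights(w)
    L = len(model.labels)
    lt = model._log_trans()
    g_state = np.zeros_like(model.state_weights)
    g_trans = np.zeros_like(model.trans_weights)
    nll = 0.0
    for ex in batch:
        S = _flat_state_scores(model, ex)
        T = ex.T
        y = ex.tags
        alpha = _forward(S, lt, L)
        beta = _backward(S, lt, L)
        logZ = float(_lse(alpha[-1] + lt[:L, L], axis=0))
        gold = float(S[np.arange(T), y].sum()) + lt[L, y[0]] + lt[y[-1], L]
        if T > 1:
            gold += float(lt[y[:-1], y[1:]].sum())
        if not np.isfinite(gold):
            raise FloatingPointError(
                "gold sequence has -inf score: it violates the transition mask"
            )
        nll += logZ - gold
        marg = np.exp(alpha + beta - logZ)  # (T, L) expected counts
        marg[np.arange(T), y] -= 1.0  # minus empirical
        if len(ex.flat_ids):
            np.add.at(
                g_state, ex.flat_ids, ex.flat_vals[:, None] * marg[ex.flat_pos]
            )
        # transitions: pairwise posteriors minus empirical, all t at once
        g_trans[L, :L] += np.exp(lt[L, :L] + S[0] + beta[0] - logZ)
        g_trans[L, y[0]] -= 1.0
        if T > 1:
            pair = np.exp(
                alpha[:-1, :, None]
                + lt[None, :L, :L]
                + (S[1:] + beta[1:])[:, None, :]
                - logZ
            )
            g_trans[:L, :L] += pair.sum(axis=0)
            np.add.at(g_trans, (y[:-1], y[1:]), -1.0)
        g_trans[:L, L] += np.exp(alpha[-1] + lt[:L, L] - logZ)
        g_trans[y[-1], L] -= 1.0
    g_trans[~model.allowed] = 0.0
    # L2 penalty
    sig2 = model.l2_sigma**2
    nll += float(w @ w) / (2 * sig2)
    grad = np.concatenate([g_state.ravel(), g_trans.ravel()])
    grad += w / sig2
    if model.masked:
        tr = grad[model.state_weights.size :].reshape(L + 1, L + 1)
        tr[~model.allowed] = 0.0
    return nll, grad


def nll_gradient(
    model: CrfModel,
    batch: Sequence[tuple[Sequence[Mapping[str, float]], Sequence[str]]],
) -> tuple[float, np.ndarray]:
    """Regularized negative log-likelihood and its gradient for a batch of
    (feature vectors, gold tags) pairs, at the model's current weights."""
    encoded = encode_dataset(model, batch)
    return _nll_gradient_encoded(model, encoded, model.get_weights())


def train(
    model: CrfModel,
    data: Sequence[tuple[Sequence[Mapping[str, float]], Sequence[str]]],
    config: TrainConfig = TrainConfig(),
    callback=None,
) -> CrfModel:
    """L-BFGS training of the convex regularized likelihood.

    Deterministic given data order and config. ``callback(iteration, nll)``
    is invoked once per accepted iterate for logging.
    """
    if not data:
        raise ValueError("training data must be non-empty")
    model.l2_sigma = config.l2_sigma
    if model.masked != config.invalid_transition_mask:
        model.masked = config.invalid_transition_mask
        L = len(model.labels)
        model.allowed = (
            bio_transition_mask(model.labels)
            if model.masked
            else np.ones((L + 1, L + 1), dtype=bool)
        )
    encoded = encode_dataset(model, data)
    it = [0]

    def objective(w: np.ndarray) -> tuple[float, np.ndarray]:
        nll, grad = _nll_gradient_encoded(model, encoded, w)
        if not np.isfinite(nll):
            raise FloatingPointError(f"non-finite objective at iteration {it[0]}")
        return nll, grad

    def on_iter(w: np.ndarray) -> None:
        it[0] += 1
        if callback is not None:
            nll, _ = _nll_gradient_encoded(model, encoded, w)
            callback(it[0], nll)

    res = minimize(
        objective,
        model.get_weights(),
        jac=True,
        method="L-BFGS-B",
        options={
            "maxiter": config.max_iterations,
            "gtol": config.gradient_tolerance,
            "ftol": 1e-12,
        },
        callback=on_iter,
    )
    model.set_weights(res.x)
    model.trained = True
    return model
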