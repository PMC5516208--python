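# Methods

This note documents the model, the synthetic study conditions, the
numerical choices, and what the shipped tests do and do not establish.

## Task and label scheme

The unit of annotation is a *mention span*: a character range in one post
covering a treatment term, carrying exactly one of five attribution
labels (`pt`, `pt-gen`, `cg`, `others`, `gen`). Attribution is decided
*locally*, from the sentence alone: a later sentence revealing that a
suggested drug was eventually taken does not retroactively change an
earlier `pt-gen` mention, and pronouns referring back to a treatment are
not mentions. This locality convention is what licenses treating the
sentence as the sequence unit for the CRF.

Spans are flat: no overlaps, no nesting. Offsets are 0-based, half-open,
into the raw post text; token indices follow the same convention under
the package tokenizer.

## The CRF

Boundaries and attribution are encoded jointly as typed BIO over 11
symbols (`O`, `B-c`, `I-c`). The model is a standard linear-chain CRF
with state features f(x_t, y_t) and a full (label+BOS) × (label+EOS)
transition table. Choices the task description leaves open were fixed as
follows:

- **Objective**: L2-regularized maximum conditional likelihood. The
  penalty is Σw²/2σ² with σ = 10 by default (weakly informative; the
  feature space is sparse indicators, so likelihood dominates).
- **Optimizer**: L-BFGS with gradient tolerance 1e-5, at most 100
  iterations by default, weights initialized at zero. The objective is
  convex, so the optimum is unique and the result is deterministic given
  data order and configuration; no randomness enters training.
- **Transition mask** (on by default): transitions violating the BIO
  grammar (`O→I-c`, `B-c→I-c'`, `I-c→I-c'` for c≠c', `BOS→I-c`) are
  assigned -inf at both training and decoding time, and their weights are
  pinned at zero. Decoded output is therefore always valid BIO and the
  repair counter stays at zero. With the mask off, invalid decoder output
  is repaired by promoting orphan `I-c` to `B-c` (repairs are counted),
  so end-to-end evaluation can never crash on a malformed sequence.
- **Tie-breaking**: Viterbi backtracking prefers the lower label index
  (with `O` at index 0). This makes decoding bit-reproducible across
  platforms and forces the all-`O` output for an all-zero model.
- **Correctness oracles**: the test suite checks Viterbi, the log
  partition function and per-position marginals against exhaustive
  enumeration of all 11^T sequences for T ≤ 4 over hundreds of random
  models (tolerance 1e-8), and the analytic gradient against central
  finite differences. These oracles are independent re-computations, not
  the shipped code paths.

## Features

Three families, each name-prefixed so families never collide:

- **lexical** (`lex:`): token, lowercase, lemma and coarse POS for
  positions i−2…i+2 (BOS/EOS padding), word shape
  (capitalization/digit/hyphen), and sentence-level flags for question
  marks, exclamation marks and @-style username mentions. Window ±2 is
  standard NER practice; raw identity features at ±2 are what make
  adjacent cue words decisive.
- **semantic** (`sem:`): per-gazetteer B/I/O dictionary-match tag at
  i−1, i, i+1. Matching is greedy leftmost-longest over lowercased token
  n-grams; a brute-force enumeration oracle property-tests it. Gazetteers
  are plain-text term lists; the shipped ~170-term autism-treatment list
  (drugs, supplements, diets, behavioural and alternative therapies, with
  inflection variants as separate entries) replaces licensed lexicons,
  which cannot be redistributed.
- **syntactic** (`syn:`): subject and predicate lemmas, signed token
  distance to each bucketed as {0, ±1, ±2, ±3–5, ±6+, none}, and
  first-person-subject indicators (subject lemma in {i, we}; a "my"/"our"
  inside the subject run). Distances are bucketed because raw integers
  explode the feature space on long sentences. Since no parse
  representation is pinned down, "path length" is realized as token
  distance; a pluggable parser could substitute tree distances behind the
  same Annotator interface. Attribution hinges on who the sentence is
  about, which is why subject identity features are included.

## Linguistic annotation

The shipped annotator is deliberately heuristic and dependency-free:
regex sentence splitting with an abbreviation guard, whitespace
tokenization that splits edge punctuation but keeps hyphens and slashes
inside tokens (`B-12` stays whole), a closed-class lexicon (~230 entries)
plus suffix rules over a coarse 11-tag POS set, suffix-stripping
lemmatization with a small irregular table, and a subject/predicate
heuristic (first non-auxiliary verb; subject = head of the longest
noun-ish run before it). It is exact on the synthetic templates and
"good enough" on simple English; it is *not* a general-purpose tagger.
Real OpenNLP/Stanford-style pipelines can be plugged in through the
`Annotator` protocol without touching anything downstream.

## Baselines

- **Dictionary detection**: gazetteer lookup, leftmost-longest. Its
  characteristic failure is recall on terms missing from the dictionary,
  which the evaluation harness exposes by scoring against a reduced
  gazetteer.
- **Lasso logistic attribution**: multinomial logistic regression with an
  L1 penalty over span features — the union of in-span token features
  (`in:`) plus the context features of the tokens flanking the span
  (`ctx:L`/`ctx:R`). The fit is delegated to scikit-learn's saga solver
  behind this module's interface (deterministic given seed and data
  order); multinomial rather than one-vs-rest so a single coherent argmax
  exists, ties broken toward the lower canonical class index. The
  classifier is trained on gold spans (the standard protocol when the
  detector is a separate component). λ defaults to 0.1; an opt-in
  `l1_lambda="cv"` mode selects it by 5-fold cross-validation over a
  fixed grid, kept optional so default runs stay fast.
- **baseline+**: CRF spans, logistic labels. By construction its
  mention-only scores equal the CRF's exactly — asserted as an invariant,
  since the span sets coincide.

## Evaluation

Exact-boundary matching, no partial credit: a prediction is correct only
with identical (post, start, end) — and identical label in typed regimes.
Precision/recall use the 0/0 → 0 convention; micro-F pools tp/fp/fn over
classes. `binary_pt` merges labels on *both* sides to {pt, non-pt} before
scoring the pt class; scoring merged five-class predictions this way can
only relax the pt score (asserted), whereas the claim that *training* on
merged labels helps is an empirical matter and is not asserted.

Cohen's κ is computed at token level over the 6-way alphabet (5 classes +
`O`), κ = (p_o − p_e)/(1 − p_e) with marginal-product expected agreement.
κ is unit-sensitive — token-level values are not comparable to
span-level ones — so the unit is part of the contract. The degenerate
case p_e = 1 (e.g. both annotators all-`O`) is reported as 1.0 with a
warning flag.

The ablation harness runs family sets × systems × regimes on a 70/30
split by post (seeded; a single split rather than cross-validation is the
default, both are reachable through the API).

## Synthetic study conditions

The generator's defaults are the package's study conditions:

- **Population**: 100 authors; posts per author ~ Geometric(mean 20);
  sentences per post ~ 1 + Poisson(1); join dates uniform over the first
  half of a 730-day window, posting timelines uniform over each author's
  remaining activity window.
- **Class mixture**: 40% of sentences carry no mention; the rest follow
  the empirical label proportions of a 500-post manual annotation of
  autism-forum posts (pt 1830, gen 1635, pt-gen 434, others 210, cg 95),
  i.e. pt ≈ 0.261, gen ≈ 0.233, pt-gen ≈ 0.062, others ≈ 0.030,
  cg ≈ 0.014 per sentence.
- **Terms**: sampled from the gazetteer with Zipf(1.2) weights over the
  lexicographically ordered term list — heavy-tailed term frequencies as
  in real forum data, deterministic given the seed.
- **Templates**: data files, one per line. Unambiguous templates give
  each class a cue word adjacent to the treatment slot that is unique to
  that class across the bank, which makes the cue_ambiguity = 0 corpus
  separable from lexical features (transition features carry the class
  across multi-token terms). Ambiguous templates are shared verbatim
  between two classes, so on those sentences the label is information-
  theoretically undecidable from text — `cue_ambiguity` is the
  probability a mention sentence uses one, and it is the difficulty dial
  standing in for real-data hardness. Defaults to 0.2.
- **Corruption**: optional character noise (swaps/drops) strictly outside
  gold spans, with offsets re-synchronized and the surface invariant
  re-checked.

What the generator does *not* emulate: real lexical diversity (template
wording is closed-vocabulary), quoting and markup, cross-sentence
coreference, label noise, out-of-gazetteer treatments, and annotator
disagreement. Consequently, near-perfect scores at cue_ambiguity = 0
establish that the pipeline recovers exactly what its assumptions
promise — they say nothing about absolute performance on real forum
text, where the same architecture historically lands far lower on the
joint task. The ordering properties (CRF over dictionary lookup when the
dictionary is incomplete; mention-only ≥ joint micro-F; binary merge
relaxing the pt score) are the structurally meaningful checks.

The longitudinal calibration check derives the expected mentions-per-post
rate for a term of Zipf rank r as μ = E[sentences/post] · (1 − p_none) ·
w_r, with per-post variance E[N]q(1−q) + q²Var(N) (N the sentence count,
q the per-sentence mention probability), and requires the empirical rate
to sit within 3 standard errors in at least 95% of join-offset bins with
at least 30 posts of support.

## Problem sizes

The test suite and the acceptance script train on a ~2,000-post corpus
(100 authors), evaluated on a 30% held-out split — large enough for
stable F estimates and tight longitudinal bins at weekly resolution,
small enough to train in about a minute on one CPU. Smaller corpora
(dozens to hundreds of posts) are used where only structural properties
are being checked.

## Numerical and degenerate-input conventions

- All sequence computations in log space; -inf encodes masked
  transitions; marginals renormalize only through the shared log-Z.
- Empty corpora, empty span lists and empty predictions are legal
  everywhere downstream of parsing (0/0 → 0 scores, empty tables);
  empty *sentences* are skipped at annotation time; empty training sets
  raise.
- Strict corpus parsing (reject malformed records, naming the line) is
  the default; lenient mode drops and counts.
- Catalogue term normalization is lowercase + whitespace collapse only —
  "chelation" and "chelating" stay distinct, matching how surface-term
  catalogues behave; an alias table can be supplied to merge variants.
- Bins with zero posts are absent from longitudinal series rather than
  zero-rate, so plots do not fabricate support.

## Known limitations

- The heuristic annotator's POS/lemma accuracy bounds the usefulness of
  syntactic features on real text; the Annotator interface is the
  escape hatch.
- Gazetteer matching is surface-level; misspellings and novel therapies
  are invisible to the semantic family and to the dictionary baseline
  (the CRF can still learn them lexically given annotated examples).
- Span features for the logistic baseline aggregate by union, which
  discards in-span ordering.
- The generator's authors post independently; thread structure is
  decorative, and no community dynamics (replies, influence) are
  modeled.
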